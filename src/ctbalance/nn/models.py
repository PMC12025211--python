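"""CPU-scale reference networks.

These are deliberately small stand-ins for full-scale backbones, sized so
that a full optimization loop runs on one CPU core in seconds:

* :class:`SmallResNet` — a residual CNN for binary slice classification:
  one stem convolution, a max-pool, two residual blocks with identity
  shortcuts, global average pooling and a linear head.
* :class:`SmallUNet` — an encoder-decoder segmenter with three resolution
  levels, 3x3 convolutions, max-pooling, nearest-neighbour upsampling and
  skip connections, ending in a 1x1 convolution over the 5 tissue codes.

Both expose ``forward(x) -> logits`` and ``backward(dlogits) -> None``
(gradients accumulate in ``grads``), with parameters/gradients as flat
name-keyed dicts consumed by the SGDM trainer.
"""

from __future__ import annotations

import numpy as np

from . import layers as L


class SmallResNet:
    """Residual classifier: stem -> pool -> 2 residual blocks -> GAP -> fc."""

    def __init__(self, channels: int = 3, n_classes: int = 2, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        c = channels
        self.params = {
            "stem_W": L.he_init(rng, (c, 1, 3, 3)), "stem_b": np.zeros(c),
            "b1a_W": L.he_init(rng, (c, c, 3, 3)), "b1a_b": np.zeros(c),
            "b1b_W": L.he_init(rng, (c, c, 3, 3)), "b1b_b": np.zeros(c),
            "b2a_W": L.he_init(rng, (c, c, 3, 3)), "b2a_b": np.zeros(c),
            "b2b_W": L.he_init(rng, (c, c, 3, 3)), "b2b_b": np.zeros(c),
            "fc_W": rng.normal(0.0, np.sqrt(1.0 / c), (c, n_classes)),
            "fc_b": np.zeros(n_classes),
        }
        self.params = {k: np.asarray(v, dtype=dtype) for k, v in self.params.items()}
        self.dtype = dtype
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = {}

    #: parameter names subject to L2 weight decay (weights, not biases)
    decay_keys = ("stem_W", "b1a_W", "b1b_W", "b2a_W", "b2b_W", "fc_W")

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        c = self._cache
        c["x"] = x
        c["h0"] = L.relu_forward(L.conv3x3_forward(x, p["stem_W"], p["stem_b"]))
        c["p0"], c["p0_r"] = L.maxpool2_forward(c["h0"])
        h = c["p0"]
        for blk in ("b1", "b2"):
            c[f"{blk}_in"] = h
            c[f"{blk}_a"] = L.relu_forward(L.conv3x3_forward(h, p[f"{blk}a_W"], p[f"{blk}a_b"]))
            c[f"{blk}_pre"] = L.conv3x3_forward(c[f"{blk}_a"], p[f"{blk}b_W"], p[f"{blk}b_b"]) + h
            h = L.relu_forward(c[f"{blk}_pre"])
            c[f"{blk}_out"] = h
        c["gap"] = h.mean(axis=(2, 3))  # (N, C)
        return c["gap"] @ p["fc_W"] + p["fc_b"]

    def backward(self, dlogits: np.ndarray) -> None:
        p, g, c = self.params, self.grads, self._cache
        g["fc_W"][...] = c["gap"].T @ dlogits
        g["fc_b"][...] = dlogits.sum(axis=0)
        dgap = dlogits @ p["fc_W"].T
        n, ch, h, w = c["b2_out"].shape
        dh = (dgap / (h * w))[:, :, None, None] * np.ones((n, ch, h, w))
        for blk in ("b2", "b1"):
            dh = L.relu_backward(c[f"{blk}_out"], dh)
            da, dWb, dbb = L.conv3x3_backward(c[f"{blk}_a"], p[f"{blk}b_W"], dh)
            g[f"{blk}b_W"][...] = dWb
            g[f"{blk}b_b"][...] = dbb
            da = L.relu_backward(c[f"{blk}_a"], da)
            din, dWa, dba = L.conv3x3_backward(c[f"{blk}_in"], p[f"{blk}a_W"], da)
            g[f"{blk}a_W"][...] = dWa
            g[f"{blk}a_b"][...] = dba
            dh = din + dh  # identity shortcut
        dp0 = L.maxpool2_backward(c["p0_r"], c["p0"], dh)
        dh0 = L.relu_backward(c["h0"], dp0)
        _, dWs, dbs = L.conv3x3_backward(c["x"], p["stem_W"], dh0)
        g["stem_W"][...] = dWs
        g["stem_b"][...] = dbs

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return L.softmax(self.forward(x))


class SmallUNet:
    """3-level U-Net with skip connections; 5-class per-pixel output."""

    def __init__(self, base_channels: int = 3, n_classes: int = 5, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = base_channels, 2 * base_channels, 4 * base_channels
        self.channels = (c1, c2, c3)
        self.params = {
            "e1_W": L.he_init(rng, (c1, 1, 3, 3)), "e1_b": np.zeros(c1),
            "e2_W": L.he_init(rng, (c2, c1, 3, 3)), "e2_b": np.zeros(c2),
            "bo_W": L.he_init(rng, (c3, c2, 3, 3)), "bo_b": np.zeros(c3),
            "d2_W": L.he_init(rng, (c2, c3 + c2, 3, 3)), "d2_b": np.zeros(c2),
            "d1_W": L.he_init(rng, (c1, c2 + c1, 3, 3)), "d1_b": np.zeros(c1),
            # classifier head sees the decoder features plus the raw input
            # intensity (a direct skip): per-pixel HU is highly class-informative
            "out_W": rng.normal(0.0, np.sqrt(2.0 / (c1 + 1)), (n_classes, c1 + 1)),
            "out_b": np.zeros(n_classes),
        }
        self.params = {k: np.asarray(v, dtype=dtype) for k, v in self.params.items()}
        self.dtype = dtype
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = {}

    decay_keys = ("e1_W", "e2_W", "bo_W", "d2_W", "d1_W", "out_W")

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, c = self.params, self._cache
        c["x"] = x
        c["e1"] = L.relu_forward(L.conv3x3_forward(x, p["e1_W"], p["e1_b"]))
        c["p1"], c["p1_r"] = L.maxpool2_forward(c["e1"])
        c["e2"] = L.relu_forward(L.conv3x3_forward(c["p1"], p["e2_W"], p["e2_b"]))
        c["p2"], c["p2_r"] = L.maxpool2_forward(c["e2"])
        c["bo"] = L.relu_forward(L.conv3x3_forward(c["p2"], p["bo_W"], p["bo_b"]))
        c["u2"] = L.upsample2_forward(c["bo"])
        c["c2"] = np.concatenate([c["u2"], c["e2"]], axis=1)
        c["d2"] = L.relu_forward(L.conv3x3_forward(c["c2"], p["d2_W"], p["d2_b"]))
        c["u1"] = L.upsample2_forward(c["d2"])
        c["c1"] = np.concatenate([c["u1"], c["e1"]], axis=1)
        c["d1"] = L.relu_forward(L.conv3x3_forward(c["c1"], p["d1_W"], p["d1_b"]))
        c["head"] = np.concatenate([c["d1"], x], axis=1)
        return L.conv1x1_forward(c["head"], p["out_W"], p["out_b"])  # (N,K,H,W)

    def backward(self, dlogits: np.ndarray) -> None:
        p, g, c = self.params, self.grads, self._cache
        c1, c2, c3 = self.channels
        dhead, dWo, dbo = L.conv1x1_backward(c["head"], p["out_W"], dlogits)
        g["out_W"][...] = dWo
        g["out_b"][...] = dbo
        dd1 = L.relu_backward(c["d1"], dhead[:, :c1])
        dc1, dW, db = L.conv3x3_backward(c["c1"], p["d1_W"], dd1)
        g["d1_W"][...] = dW
        g["d1_b"][...] = db
        du1, de1_skip = dc1[:, :c2], dc1[:, c2:]
        dd2 = L.upsample2_backward(du1)
        dd2 = L.relu_backward(c["d2"], dd2)
        dc2, dW, db = L.conv3x3_backward(c["c2"], p["d2_W"], dd2)
        g["d2_W"][...] = dW
        g["d2_b"][...] = db
        du2, de2_skip = dc2[:, :c3], dc2[:, c3:]
        dbo_ = L.upsample2_backward(du2)
        dbo_ = L.relu_backward(c["bo"], dbo_)
        dp2, dW, db = L.conv3x3_backward(c["p2"], p["bo_W"], dbo_)
        g["bo_W"][...] = dW
        g["bo_b"][...] = db
        de2 = L.maxpool2_backward(c["p2_r"], c["p2"], dp2) + de2_skip
        de2 = L.relu_backward(c["e2"], de2)
        dp1, dW, db = L.conv3x3_backward(c["p1"], p["e2_W"], de2)
        g["e2_W"][...] = dW
        g["e2_b"][...] = db
        de1 = L.maxpool2_backward(c["p1_r"], c["p1"], dp1) + de1_skip
        de1 = L.relu_backward(c["e1"], de1)
        _, dW, db = L.conv3x3_backward(c["x"], p["e1_W"], de1)
        g["e1_W"][...] = dW
        g["e1_b"][...] = db

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return L.softmax(self.forward(x), axis=1)
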