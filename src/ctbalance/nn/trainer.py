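"""SGD-with-momentum trainer consuming the full hyperparameter design.

Semantics follow the classic SGDM family: velocity
``v <- momentum * v - lr * g`` with L2 regularization added to the weight
gradients, and the *global* gradient norm clipped at
``gradient_threshold`` before each update. Every hyperparameter in the
design demonstrably changes training: epochs set the optimizer step
count, batch size the steps per epoch, and the per-step clipped gradient
norms are recorded so the clipping contract is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imbalance import Hyperparameters
from .layers import weighted_softmax_ce


@dataclass
class TrainingRecord:
    losses: list = field(default_factory=list)
    grad_norms: list = field(default_factory=list)  # post-clipping, per step
    n_steps: int = 0
    n_epochs: int = 0


def _flatten_labels(logits: np.ndarray, labels: np.ndarray) -> tuple:
    """(N,K) stays; (N,K,H,W) pixel logits flatten to rows."""
    if logits.ndim == 2:
        return logits, labels.astype(np.intp)
    n, k, h, w = logits.shape
    flat = logits.transpose(0, 2, 3, 1).reshape(-1, k)
    return flat, labels.reshape(-1).astype(np.intp)


def _unflatten_grad(dflat: np.ndarray, shape: tuple) -> np.ndarray:
    if len(shape) == 2:
        return dflat
    n, k, h, w = shape
    return dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2)


def sgdm_train(model, X: np.ndarray, y: np.ndarray, hp: Hyperparameters,
               class_weights: np.ndarray, seed: int = 0) -> TrainingRecord:
    """Train ``model`` in place; returns the per-step training record."""
    hp.validate()
    rng = np.random.default_rng(seed)
    rec = TrainingRecord()
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    n = len(X)
    bs = int(hp.batch_size)
    w = np.asarray(class_weights, dtype=float)
    for _epoch in range(int(hp.epochs)):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            logits = model.forward(X[idx])
            flat, lab = _flatten_labels(logits, y[idx])
            loss, dflat = weighted_softmax_ce(flat, lab, w)
            model.backward(_unflatten_grad(dflat, logits.shape))
            # L2 weight decay on weight tensors only
            for k in model.decay_keys:
                model.grads[k] += hp.l2_regularization * model.params[k]
            gnorm = float(np.sqrt(sum(float((g**2).sum()) for g in model.grads.values())))
            scale = min(1.0, hp.gradient_threshold / gnorm) if gnorm > 0 else 1.0
            for k, g in model.grads.items():
                velocity[k] = hp.momentum * velocity[k] - hp.learning_rate * (g * scale)
                model.params[k] += velocity[k]
            rec.losses.append(loss)
            rec.grad_norms.append(gnorm * scale)
            rec.n_steps += 1
        rec.n_epochs += 1
    return rec


def predict_in_batches(model, X: np.ndarray, batch: int = 64) -> np.ndarray:
    out = [model.predict_proba(X[i:i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(out, axis=0)
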