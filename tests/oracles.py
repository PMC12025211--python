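"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit pixel loops, direct
linear algebra, Monte-Carlo estimates — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_confusion(pred, true, cls: int) -> tuple:
    """One-vs-rest TP/FP/FN/TN for one class by explicit pixel iteration."""
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred).ravel().tolist(), np.asarray(true).ravel().tolist()):
        if p == cls and t == cls:
            tp += 1
        elif p == cls:
            fp += 1
        elif t == cls:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_overlap_scores(pred, true, cls: int) -> dict:
    tp, fp, fn, tn = brute_confusion(pred, true, cls)
    out = {}
    out["jaccard"] = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    out["dice"] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else 1.0
    out["specificity"] = tn / (tn + fp) if (tn + fp) else 1.0
    return out


def brute_boundary(mask) -> list:
    """(row, col) pixels of the mask with a 4-neighbour outside the mask."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if not m[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not m[ni, nj]:
                    pts.append((i, j))
                    break
    return pts


def brute_msd(pred_mask, true_mask, spacing: float, mode: str = "directed") -> float:
    pb, tb = brute_boundary(pred_mask), brute_boundary(true_mask)
    if not pb or not tb:
        return float("nan")

    def directed(src, dst):
        total = 0.0
        for (i, j) in src:
            total += min(math.hypot(i - a, j - b) for (a, b) in dst)
        return total / len(src)

    if mode == "directed":
        return directed(pb, tb) * spacing
    return 0.5 * (directed(pb, tb) + directed(tb, pb)) * spacing


def brute_bland_altman(pairs) -> dict:
    diffs = [p - t for p, t in pairs]
    n = len(diffs)
    mean = sum(diffs) / n
    sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = sum(1 for d in diffs if lo < d < hi) / n
    return {"mean": mean, "sd": sd, "lower": lo, "upper": hi, "within": within}


def brute_area(mask, cls: int, spacing: float, native: int, current: int) -> float:
    count = sum(1 for v in np.asarray(mask).ravel().tolist() if v == cls)
    return count * spacing * spacing * (native / current) ** 2


def brute_r_squared(pred, ref) -> float:
    x = list(map(float, ref))
    y = list(map(float, pred))
    n = len(x)
    xb, yb = sum(x) / n, sum(y) / n
    sxy = sum((a - xb) * (b - yb) for a, b in zip(x, y))
    sxx = sum((a - xb) ** 2 for a in x)
    syy = sum((b - yb) ** 2 for b in y)
    return sxy * sxy / (sxx * syy)


def matern52(xa, xb, length_scales, variance) -> float:
    r = math.sqrt(sum(((a - b) / l) ** 2 for a, b, l in zip(xa, xb, length_scales)))
    s = math.sqrt(5.0) * r
    return variance * (1.0 + s + s * s / 3.0) * math.exp(-s)


def gp_posterior_oracle(X, y, Xq, length_scales, variance, alpha,
                        normalize_y: bool = True) -> tuple:
    """Posterior mean/sd by direct kernel-matrix linear algebra."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xq = np.asarray(Xq, dtype=float)
    if normalize_y:
        y_mean, y_std = y.mean(), y.std()
        y_std = y_std if y_std > 0 else 1.0
    else:
        y_mean, y_std = 0.0, 1.0
    yn = (y - y_mean) / y_std
    n = len(X)
    K = np.array([[matern52(X[i], X[j], length_scales, variance) for j in range(n)]
                  for i in range(n)]) + alpha * np.eye(n)
    Ks = np.array([[matern52(q, X[j], length_scales, variance) for j in range(n)]
                   for q in Xq])
    Kinv_y = np.linalg.solve(K, yn)
    mu = Ks @ Kinv_y * y_std + y_mean
    var = np.empty(len(Xq))
    Kinv = np.linalg.inv(K)
    for i, q in enumerate(Xq):
        kss = matern52(q, q, length_scales, variance)
        var[i] = kss - Ks[i] @ Kinv @ Ks[i]
    var = np.clip(var, 0.0, None) * y_std**2
    return mu, np.sqrt(var)


def ei_monte_carlo(mu: float, sigma: float, incumbent: float,
                   n: int = 10**6, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(mu, sigma, size=n)
    return float(np.maximum(incumbent - draws, 0.0).mean())
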