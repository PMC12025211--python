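"""Bayesian optimization of the mixed design space.

The objective is the inverse F1 score, 1/F1 = (Precision + Recall) /
(2 x Precision x Recall), minimized over the design vector
d = {d_h, d_a, d_c}. A Gaussian-process surrogate (Matérn-5/2 kernel with
per-dimension length-scales, fitted by marginal-likelihood maximization)
models the objective on the unit cube; expected improvement (in its
minimization form) picks the next design to evaluate.

Mixed variable types are handled by encoding: log-scaled continuous axes
are mapped through log before affine scaling to [0, 1]; integer axes are
scaled continuously and decoded by rounding to the nearest feasible
integer.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize as spopt
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .imbalance import HYPERPARAMETER_BOUNDS
from .metrics import ConfusionCounts

logger = logging.getLogger(__name__)

#: Objective reported when F1 = 0 (keeps the surrogate finite).
OBJECTIVE_CAP = 1e6

VARIABLE_KINDS = ("log_continuous", "continuous", "integer")


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str
    lower: float
    upper: float

    def __post_init__(self):
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper) and self.lower < self.upper):
            raise ValueError(f"invalid bounds for {self.name}: [{self.lower}, {self.upper}]")
        if self.kind == "log_continuous" and self.lower <= 0:
            raise ValueError(f"log-scaled variable {self.name} needs positive bounds")


@dataclass
class DesignSpace:
    """Ordered list of named variables defining the search cube."""

    variables: list

    @property
    def dim(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    # -- encoding ----------------------------------------------------------
    def encode(self, values: dict) -> np.ndarray:
        x = np.empty(self.dim)
        for i, v in enumerate(self.variables):
            val = values[v.name]
            if not (v.lower - 1e-12 <= val <= v.upper + 1e-12):
                raise ValueError(f"{v.name}={val} outside [{v.lower}, {v.upper}]")
            if v.kind == "log_continuous":
                x[i] = (np.log(val) - np.log(v.lower)) / (np.log(v.upper) - np.log(v.lower))
            else:
                x[i] = (val - v.lower) / (v.upper - v.lower)
        return np.clip(x, 0.0, 1.0)

    def decode(self, x: np.ndarray) -> dict:
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        out = {}
        for i, v in enumerate(self.variables):
            if v.kind == "log_continuous":
                val = np.exp(np.log(v.lower) + x[i] * (np.log(v.upper) - np.log(v.lower)))
                out[v.name] = float(min(max(val, v.lower), v.upper))
            elif v.kind == "integer":
                out[v.name] = int(np.clip(round(v.lower + x[i] * (v.upper - v.lower)),
                                          v.lower, v.upper))
            else:
                out[v.name] = float(v.lower + x[i] * (v.upper - v.lower))
        return out

    # -- constructors ------------------------------------------------------
    @classmethod
    def hyperparameters(cls) -> "DesignSpace":
        """The six trainer hyperparameters d_h."""
        return cls([Variable(n, kind, lo, hi) for n, (lo, hi, kind) in HYPERPARAMETER_BOUNDS.items()])

    @classmethod
    def detection(cls, n_minority: int, n_majority: int, class_weight_minima,
                  with_cdv: bool = True, weight_span: float = 10.0) -> "DesignSpace":
        """d_h (+ d_a in [n_min/n_maj, 1] and per-class d_c when CDVs are on).

        The d_a lower bound is the raw class ratio (no augmentation); the
        upper bound is exact 1:1 balance. Each d_c axis spans from its
        task minimum up to ``weight_span`` times that minimum (at least 1).
        """
        space = cls.hyperparameters()
        if with_cdv:
            lo = max(1e-6, n_minority / n_majority)
            space.variables.append(Variable("d_a", "continuous", lo, 1.0))
            space.variables.extend(_weight_variables(class_weight_minima, weight_span))
        return space

    @classmethod
    def segmentation(cls, class_weight_minima, with_cdv: bool = True,
                     weight_span: float = 10.0) -> "DesignSpace":
        space = cls.hyperparameters()
        if with_cdv:
            space.variables.extend(_weight_variables(class_weight_minima, weight_span))
        return space


def _weight_variables(minima, span: float) -> list:
    minima = np.asarray(minima, dtype=float)
    if span <= 1.0:
        raise ValueError("weight_span must exceed 1")
    return [Variable(f"d_c_{k}", "continuous", float(m), float(max(1.0, span * m)))
            for k, m in enumerate(minima)]


def objective_from_counts(counts: ConfusionCounts, foreground_classes,
                          average: str = "macro", cap: float = OBJECTIVE_CAP) -> float:
    """1/F1 from confusion counts; F1 = 0 (or no items at all) caps at ``cap``.

    Multi-class counts are reduced by macro-averaging per-class F1 over the
    foreground classes before inversion (``average='micro'`` pools counts
    instead).
    """
    idx = np.asarray(list(foreground_classes))
    if average == "macro":
        f1 = float(np.mean(_f1_per_class(counts, idx)))
    elif average == "micro":
        tp = counts.tp[idx].sum()
        fp = counts.fp[idx].sum()
        fn = counts.fn[idx].sum()
        f1 = float(2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) > 0 else 0.0
    else:
        raise ValueError(f"unknown average {average!r}")
    if f1 <= 0:
        logger.warning("F1 = 0; returning capped objective %.1e", cap)
        return cap
    return 1.0 / f1


def _f1_per_class(counts: ConfusionCounts, idx: np.ndarray) -> np.ndarray:
    tp, fp, fn = counts.tp[idx], counts.fp[idx], counts.fn[idx]
    denom = 2 * tp + fp + fn
    out = np.zeros(len(idx), dtype=float)
    nz = denom > 0
    out[nz] = 2 * tp[nz] / denom[nz]
    return out  # absent class with no predictions counts as F1=0 here


@dataclass
class Observation:
    values: dict
    x: np.ndarray
    objective: float
    index: int
    error: str | None = None


@dataclass
class SurrogateState:
    """Fitted GP posterior over the encoded cube plus the incumbent."""

    gp: GaussianProcessRegressor
    X: np.ndarray
    y: np.ndarray
    incumbent_objective: float
    incumbent_x: np.ndarray

    def predict(self, X) -> tuple:
        mu, sd = self.gp.predict(np.atleast_2d(X), return_std=True)
        return mu, np.maximum(sd, 0.0)


def gp_fit(X: np.ndarray, y: np.ndarray, noise: float = 1e-8,
           n_restarts: int = 2, seed: int = 0,
           kernel_config: dict | None = None) -> SurrogateState:
    """Fit the Matérn-5/2 ARD surrogate by marginal-likelihood maximization.

    ``noise`` is an observation-noise floor added to the kernel diagonal
    for numerical stability; jitter escalates automatically on a
    non-positive-definite covariance. ``kernel_config`` may pin the kernel:
    ``{"length_scale": array, "constant_value": float, "optimize": False}``
    skips the marginal-likelihood fit entirely.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 observations to fit the surrogate")
    cfg = kernel_config or {}
    kernel = ConstantKernel(cfg.get("constant_value", 1.0), (1e-3, 1e3)) * Matern(
        length_scale=cfg.get("length_scale", np.ones(X.shape[1])),
        length_scale_bounds=(1e-2, 1e2), nu=2.5,
    )
    optimizer = None if cfg.get("optimize", True) is False else "fmin_l_bfgs_b"
    last_err = None
    for jitter in (noise, 1e-6, 1e-4):
        try:
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=jitter, normalize_y=True, optimizer=optimizer,
                n_restarts_optimizer=n_restarts, random_state=seed,
            )
            with warnings.catch_warnings():
                # length-scales pinned at their bounds are routine on flat
                # or capped objectives; not actionable inside the loop
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, y)
            best = int(np.argmin(y))
            return SurrogateState(gp, X, y, float(y[best]), X[best].copy())
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare
            last_err = err
    raise np.linalg.LinAlgError(f"GP covariance singular even with jitter: {last_err}")


def expected_improvement(mu, sigma, incumbent: float) -> np.ndarray:
    """EI for minimization: (inc - mu) Phi(z) + sigma phi(z), z = (inc - mu)/sigma.

    With sigma = 0 this degenerates to max(incumbent - mu, 0).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    imp = incumbent - mu
    out = np.maximum(imp, 0.0)
    pos = sigma > 0
    if np.any(pos):
        z = imp[pos] / sigma[pos]
        out[pos] = imp[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return out


def propose_next(state: SurrogateState, space: DesignSpace,
                 rng: np.random.Generator, n_candidates: int = 2048) -> dict:
    """Maximize EI by uniform cube sampling plus local refinement."""
    cand = rng.uniform(size=(n_candidates, space.dim))
    mu, sd = state.predict(cand)
    ei = expected_improvement(mu, sd, state.incumbent_objective)

    def neg_ei(x):
        m, s = state.predict(x.reshape(1, -1))
        return -float(expected_improvement(m, s, state.incumbent_objective)[0])

    order = np.argsort(ei)[::-1]
    best_x, best_ei = cand[order[0]], ei[order[0]]
    for i in order[:4]:  # multistart local refinement from the top candidates
        res = spopt.minimize(neg_ei, cand[i], bounds=[(0.0, 1.0)] * space.dim,
                             method="L-BFGS-B")
        if -res.fun > best_ei:
            best_x, best_ei = res.x, -res.fun
    return space.decode(best_x)


@dataclass
class OptimizationResult:
    best_values: dict
    best_objective: float
    history: list  # list[Observation]
    seed: int
    budget: int

    def incumbent_trace(self) -> np.ndarray:
        return np.minimum.accumulate([o.objective for o in self.history])


def optimize(objective_fn, space: DesignSpace, budget: int = 40,
             n_init: int | None = None, seed: int = 0,
             cap: float = OBJECTIVE_CAP, n_candidates: int = 2048) -> OptimizationResult:
    """Full surrogate loop: Latin-hypercube initialization, then
    fit -> expected improvement -> evaluate until the budget is spent.

    ``objective_fn`` receives a decoded ``{name: value}`` dict; exceptions
    it raises are logged and recorded as the capped objective so one
    failed training run cannot abort the search.
    """
    if n_init is None:
        n_init = max(5, 2 * space.dim)
    n_init = min(n_init, budget - 1)
    if not budget > n_init >= 2:
        raise ValueError(f"need budget > n_init >= 2, got budget={budget}, n_init={n_init}")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=space.dim, seed=rng)
    X_init = sampler.random(n_init)

    history: list = []

    def _evaluate(x: np.ndarray, idx: int) -> Observation:
        values = space.decode(x)
        try:
            obj = float(objective_fn(values))
        except Exception as err:  # noqa: BLE001 - survey loop must continue
            logger.warning("objective failed at iteration %d: %s", idx, err)
            return Observation(values, np.asarray(x, dtype=float), cap, idx, error=str(err))
        return Observation(values, np.asarray(x, dtype=float), obj, idx)

    for i in range(n_init):
        history.append(_evaluate(X_init[i], i))

    for i in range(n_init, budget):
        X = np.stack([o.x for o in history])
        y = np.array([o.objective for o in history])
        state = gp_fit(X, y, seed=int(rng.integers(2**31 - 1)))
        values = propose_next(state, space, rng, n_candidates=n_candidates)
        history.append(_evaluate(space.encode(values), i))

    best = min(history, key=lambda o: o.objective)
    return OptimizationResult(best.values, best.objective, history, seed, budget)
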