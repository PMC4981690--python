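"""Feed-forward network mapping (α₁₂, α₂₃, α₁₃) to the centroid surrogate β″.

A 3-input → 10-hidden → 1-output network with logistic hidden activation
and identity output approximates each class's k-means centroid β′ as a
weighted combination of the α terms (β′ ≅ Σ γ_ij α_ij).  Training uses
resilient backpropagation (RPROP+) on the sum-of-squares error, stopping
when the largest absolute error-gradient component drops below a
threshold — the stopping semantics of the R ``neuralnet`` tool whose
``hidden = 10, threshold = 0.01`` settings this mirrors.  The whole model
is 51 weights; leave-one-out retraining is cheap and is the validation
route, with a χ² statistic comparing predictions to expected centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .clustering import ClusterModel

N_IN, N_HIDDEN, N_OUT = 3, 10, 1
N_WEIGHTS = N_IN * N_HIDDEN + N_HIDDEN + N_HIDDEN * N_OUT + N_OUT  # = 51


@dataclass
class TrainingConfig:
    hidden_units: int = N_HIDDEN
    stop_threshold: float = 0.01  # on max |dE/dw|
    max_steps: int = 100_000
    seed: int = 0
    input_scaling: str = "none"  # or "standardize"

    def __post_init__(self) -> None:
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")
        if self.input_scaling not in ("none", "standardize"):
            raise ValueError(f"bad input_scaling {self.input_scaling!r}")


@dataclass
class ANNModel:
    """Weights of the 3→hidden→1 network plus training diagnostics."""

    w1: np.ndarray  # (hidden, 3)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    converged: bool
    training_error: float
    n_steps: int
    x_center: np.ndarray = field(default_factory=lambda: np.zeros(N_IN))
    x_scale: np.ndarray = field(default_factory=lambda: np.ones(N_IN))

    @property
    def n_weights(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + 1


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(model_params, X):
    w1, b1, w2, b2 = model_params
    h = _logistic(X @ w1.T + b1)
    return h, h @ w2 + b2


def _gradients(params, X, y):
    w1, b1, w2, b2 = params
    h, yhat = _forward(params, X)
    r = yhat - y  # (n,)
    gw2 = r @ h
    gb2 = float(r.sum())
    dh = np.outer(r, w2) * h * (1.0 - h)  # (n, hidden)
    gw1 = dh.T @ X
    gb1 = dh.sum(axis=0)
    err = 0.5 * float(r @ r)
    return (gw1, gb1, gw2, gb2), err


def train(X: np.ndarray, y: np.ndarray, cfg: Optional[TrainingConfig] = None) -> ANNModel:
    """Fit the network by RPROP+ until the gradient threshold is met.

    ``X`` holds one (α₁₂, α₂₃, α₁₃) triple per row, ``y`` the target β′
    values.  Weight initialization is seeded (standard-normal, as the
    reference tool does); non-convergence within ``max_steps`` returns the
    model with ``converged=False`` and a warning rather than raising.
    """
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != N_IN:
        raise ValueError(f"X must be (n, {N_IN})")
    if len(X) != len(y) or len(X) < 2:
        raise ValueError("need >= 2 training pairs with matching lengths")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training data")

    center = np.zeros(N_IN)
    scale = np.ones(N_IN)
    if cfg.input_scaling == "standardize":
        center = X.mean(axis=0)
        sd = X.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - center) / scale

    rng = np.random.default_rng(cfg.seed)
    nh = cfg.hidden_units
    params = [rng.standard_normal((nh, N_IN)), rng.standard_normal(nh),
              rng.standard_normal(nh), float(rng.standard_normal())]

    # RPROP+ state: per-weight step sizes and previous gradients
    steps = [np.full_like(np.atleast_1d(p), 0.1, dtype=float) for p in
             [params[0], params[1], params[2], np.array([params[3]])]]
    prev = [np.zeros_like(s) for s in steps]
    prev_delta = [np.zeros_like(s) for s in steps]
    eta_minus, eta_plus = 0.5, 1.2
    step_min, step_max = 1e-10, 50.0

    converged = False
    err = np.inf
    prev_err = np.inf
    it = 0
    for it in range(1, cfg.max_steps + 1):
        flat_params = [params[0], params[1], params[2], np.array([params[3]])]
        grads, err = _gradients((flat_params[0], flat_params[1],
                                 flat_params[2], float(flat_params[3][0])), Xs, y)
        grads = [grads[0], grads[1], grads[2], np.array([grads[3]])]
        gmax = max(float(np.abs(g).max()) for g in grads)
        if gmax < cfg.stop_threshold:
            converged = True
            break
        for k in range(4):
            sign = prev[k] * grads[k]
            steps[k] = np.where(sign > 0, np.minimum(steps[k] * eta_plus, step_max),
                                np.where(sign < 0,
                                         np.maximum(steps[k] * eta_minus, step_min),
                                         steps[k]))
            delta = np.where(grads[k] > 0, -steps[k],
                             np.where(grads[k] < 0, steps[k], 0.0))
            # RPROP+ backtracking: revert the last move on sign change if
            # the error grew, and zero the stored gradient there
            if err > prev_err:
                delta = np.where(sign < 0, -prev_delta[k], delta)
            grads[k] = np.where(sign < 0, 0.0, grads[k])
            flat_params[k] = flat_params[k] + delta
            prev_delta[k] = delta
            prev[k] = grads[k]
        params = [flat_params[0], flat_params[1], flat_params[2],
                  float(flat_params[3][0])]
        prev_err = err

    if not converged:
        warnings.warn(f"RPROP did not reach gradient threshold "
                      f"{cfg.stop_threshold} within {cfg.max_steps} steps "
                      f"(final SSE/2 = {err:.4g})", stacklevel=2)
    return ANNModel(params[0], params[1], params[2], params[3],
                    converged, float(err), it, center, scale)


def predict(model: ANNModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; returns β″ per input row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = (X - model.x_center) / model.x_scale
    _, yhat = _forward((model.w1, model.b1, model.w2, model.b2), Xs)
    return yhat


def chi_squared(predicted: Sequence[float], expected: Sequence[float]) -> tuple:
    """χ² = Σ(obs − exp)²/exp with df = n − 1; expected must be positive."""
    obs = np.asarray(predicted, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("length mismatch")
    if np.any(exp <= 0):
        raise ValueError("expected values must be positive")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, len(obs) - 1


@dataclass
class LoocvResult:
    predictions: Mapping[str, float]  # seq_id -> beta''
    expected: Mapping[str, float]  # seq_id -> class centroid beta'
    chi2: float
    df: int
    matches: Mapping[str, bool]  # nearest centroid == own class


def loo_predictions(X: np.ndarray, y: np.ndarray,
                    cfg: Optional[TrainingConfig] = None) -> np.ndarray:
    """Plain leave-one-out regression: train on n−1 rows, predict the rest."""
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    out = np.empty(len(X))
    mask = np.ones(len(X), dtype=bool)
    for i in range(len(X)):
        mask[i] = False
        sub = TrainingConfig(cfg.hidden_units, cfg.stop_threshold, cfg.max_steps,
                             cfg.seed + i, cfg.input_scaling)
        model = train(X[mask], y[mask], sub)
        out[i] = float(predict(model, X[i:i + 1])[0])
        mask[i] = True
    return out


def loocv(alphas: Mapping[str, np.ndarray], labels: Mapping[str, str],
          centroids: ClusterModel, cfg: Optional[TrainingConfig] = None) -> LoocvResult:
    """Leave-one-out validation against the class centroids.

    For every sequence the network is retrained on the remainder (targets
    are each training sequence's class centroid β′) and the held-out β″ is
    compared with that sequence's expected centroid; agreement is
    summarized by χ² with df = n − 1 and by nearest-centroid match flags.
    """
    cfg = cfg or TrainingConfig()
    ids = sorted(alphas.keys())
    X = np.array([np.asarray(alphas[i], dtype=float) for i in ids])
    y = np.array([centroids.centroid_of(labels[i]) for i in ids])
    for cls in set(labels[i] for i in ids):
        if sum(1 for i in ids if labels[i] == cls) < 2:
            warnings.warn(f"class {cls} has < 2 members; its leave-one-out "
                          "folds train without that class", stacklevel=2)
    preds = loo_predictions(X, y, cfg)
    chi2, df = chi_squared(preds, y)
    cents = centroids.centroids
    matches = {}
    for i, sid in enumerate(ids):
        nearest = min(cents, key=lambda c: abs(cents[c] - preds[i]))
        matches[sid] = bool(nearest == labels[sid])
    return LoocvResult(dict(zip(ids, preds)), dict(zip(ids, y)), chi2, df, matches)
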