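"""Lasso regression by proximal gradient descent -- plaintext reference.

Minimizes ``F(w) = (1/n) ||Xw - y||_2^2 + lam * ||w||_1`` with the iteration

    w  <-  Proxy(w - eta_t * (2/n) X^T (Xw - y),  tau)

where ``Proxy`` is component-wise soft thresholding and ``tau`` is the
threshold: ``lam`` as literally specified (default), or ``eta_t * lam`` when
``ista_scaling`` is on (the canonical ISTA choice, which makes the iteration
a true proximal step and guarantees monotone descent for ``eta_t <= 1/L``).
The stopping statistic is the relative squared update
``||w_new - w_old||^2 / ||w_old||^2`` compared against ``tolerance``; with
``w_0 = 0`` the first ratio is 0/0, treated as +inf so training never stops
before taking a step.

This module is the exact functional specification the secure trainer must
reproduce; the fidelity tests compare the two iteration for iteration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DIVERGENCE_FACTOR = 1e6


class DivergenceError(RuntimeError):
    """The objective exploded; the step-size rule is unsuitable."""


class UndefinedRSquaredError(ValueError):
    """R^2 is undefined (constant target or zero denominator)."""


@dataclass
class GDConfig:
    """Hyper-parameters of (secure or plaintext) proximal gradient descent.

    ``lam`` and ``tolerance`` default to the operating point used throughout
    the docs (lam=0.001, tolerance=1e-4).  ``step_rule`` is ``"harmonic"``
    (eta_t = eta0 / (1+t), always convergent for convex objectives) or
    ``"constant"`` (eta_t = eta0, the textbook ISTA schedule).  ``eta0=None``
    means the data-driven rule ``0.1 / max(X^T X)``.
    """

    lam: float = 0.001
    tolerance: float = 1e-4
    max_iter: int = 100
    eta0: float | None = None
    step_rule: str = "harmonic"
    ista_scaling: bool = False
    fit_intercept: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.step_rule not in ("harmonic", "constant"):
            raise ValueError(f"unknown step_rule {self.step_rule!r}")

    def step_size(self, eta0: float, t: int) -> float:
        return eta0 / (1 + t) if self.step_rule == "harmonic" else eta0


@dataclass
class LassoModel:
    weights: np.ndarray
    intercept: float
    iterations_used: int
    objective: float | None
    stop_reason: str  # "tolerance" | "max_iter"

    def to_json(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "iterations_used": self.iterations_used,
            "objective": self.objective,
            "stop_reason": self.stop_reason,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))


@dataclass
class EvalReport:
    r_squared: float
    mse: float
    mae: float
    y_mean: float

    def to_json(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> float:
    """F(w) = (1/n)||Xw - y||_2^2 + lam ||w||_1."""
    X, y, w = np.asarray(X, float), np.asarray(y, float), np.asarray(w, float)
    if X.shape[0] != y.shape[0] or X.shape[1] != w.shape[0]:
        raise ValueError("inconsistent shapes")
    r = X @ w - y
    return float(r @ r / X.shape[0] + lam * np.abs(w).sum())


def calc_gradient(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of the smooth part: (2/n) X^T (Xw - y)."""
    X, y, w = np.asarray(X, float), np.asarray(y, float), np.asarray(w, float)
    if X.shape[0] != y.shape[0] or X.shape[1] != w.shape[0]:
        raise ValueError("inconsistent shapes")
    return 2.0 / X.shape[0] * (X.T @ (X @ w - y))


def proxy(w: np.ndarray, lam: float) -> np.ndarray:
    """Component-wise soft threshold: shrink by lam, zero when |w_i| <= lam."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    w = np.asarray(w, float)
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def proxy_via_bits(w: np.ndarray, lam: float) -> np.ndarray:
    """Soft threshold written with comparison bits, as executed on shares:
    a*(w - lam) + b*(w + lam) with a = (w > lam), b = (w < -lam).
    Identical to :func:`proxy` for every input."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    w = np.asarray(w, float)
    a = (w > lam).astype(float)
    b = (w < -lam).astype(float)
    return a * (w - lam) + b * (w + lam)


def update_difference(w_new: np.ndarray, w_old: np.ndarray) -> float:
    """||w_new - w_old||^2 / ||w_old||^2; +inf when w_old is the zero vector."""
    w_new, w_old = np.asarray(w_new, float), np.asarray(w_old, float)
    if w_new.shape != w_old.shape:
        raise ValueError("length mismatch")
    den = float(w_old @ w_old)
    num = float((w_new - w_old) @ (w_new - w_old))
    return math.inf if den == 0.0 else num / den


def initial_step_size(X: np.ndarray) -> float:
    """0.1 divided by the largest entry of X^T X."""
    X = np.asarray(X, float)
    g = float((X.T @ X).max())
    if g <= 0:
        raise ValueError("X^T X has no positive entry; cannot set a step size")
    return 0.1 / g


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _with_intercept(X: np.ndarray, fit_intercept: bool) -> np.ndarray:
    return np.column_stack([X, np.ones(X.shape[0])]) if fit_intercept else X


def train_plaintext(X: np.ndarray, y: np.ndarray, cfg: GDConfig) -> LassoModel:
    """Proximal gradient descent on plaintext data; deterministic.

    With ``fit_intercept`` an unpenalized all-ones column is appended and its
    coefficient is excluded from the soft threshold.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xe = _with_intercept(X, cfg.fit_intercept)
    m = Xe.shape[1]
    w = np.zeros(m)
    eta0 = cfg.eta0 if cfg.eta0 is not None else initial_step_size(Xe)
    f0 = objective(Xe, y, w, cfg.lam)
    stop_reason = "max_iter"
    t_used = cfg.max_iter
    for t in range(cfg.max_iter):
        eta = cfg.step_size(eta0, t)
        tau = eta * cfg.lam if cfg.ista_scaling else cfg.lam
        u = w - eta * calc_gradient(Xe, y, w)
        w_new = proxy_via_bits(u, tau)
        if cfg.fit_intercept:
            w_new[-1] = u[-1]
        ud = update_difference(w_new, w)
        w = w_new
        if objective(Xe, y, w, cfg.lam) > DIVERGENCE_FACTOR * max(f0, 1e-300):
            raise DivergenceError("objective exceeded 1e6 x its initial value")
        if ud < cfg.tolerance:
            stop_reason = "tolerance"
            t_used = t + 1
            break
    weights = w[:-1] if cfg.fit_intercept else w
    intercept = float(w[-1]) if cfg.fit_intercept else 0.0
    return LassoModel(
        weights=weights,
        intercept=intercept,
        iterations_used=t_used,
        objective=objective(Xe, y, w, cfg.lam),
        stop_reason=stop_reason,
    )


def r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination with squared residual sums."""
    y, y_pred = np.asarray(y, float), np.asarray(y_pred, float)
    if y.shape != y_pred.shape:
        raise ValueError("length mismatch")
    den = float(((y - y.mean()) ** 2).sum())
    if den == 0.0:
        raise UndefinedRSquaredError("target is constant; R^2 undefined")
    num = float(((y - y_pred) ** 2).sum())
    return 1.0 - num / den


def evaluate(model: LassoModel, X: np.ndarray, y: np.ndarray) -> EvalReport:
    X, y = np.asarray(X, float), np.asarray(y, float)
    y_pred = X @ model.weights + model.intercept
    return EvalReport(
        r_squared=r_squared(y, y_pred),
        mse=float(((y - y_pred) ** 2).mean()),
        mae=float(np.abs(y - y_pred).mean()),
        y_mean=float(y.mean()),
    )
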