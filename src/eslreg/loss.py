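"""The exponential squared loss, its objective, score, and the
fixed-gamma maximiser.

The loss is Phi_gamma(t) = 1 - exp(-t^2 / gamma).  It is bounded by 1,
so no single observation can dominate the fit; gamma trades robustness
(small gamma) against efficiency (large gamma, where the estimator
approaches least squares).

Estimation at fixed gamma maximises

    l_n(beta) = sum_i exp(-(y_i - x_i' beta)^2 / gamma),

equivalently minimises the total loss, since
l_n(beta) = n - sum_i Phi_gamma(r_i).  Stationary points satisfy the
weighted normal equations with weights w_i = exp(-r_i^2/gamma), which
motivates the iteratively reweighted least squares (IRLS) solver below.
The objective is multimodal; the solver performs monotone ascent from
the supplied starting value (in the full pipeline, the MM estimate or
the previous outer iterate) and reports local convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RegressionData, check_full_rank
from .exceptions import (
    DegenerateFitError,
    DimensionError,
    InvalidParameterError,
)
from .scale import pseudo_outlier_set

__all__ = [
    "esl_loss",
    "esl_objective",
    "esl_score",
    "fit_esl_fixed_gamma",
    "ESLFit",
]


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not np.isfinite(gamma) or gamma <= 0.0:
        raise InvalidParameterError(f"gamma must be positive, got {gamma}")
    return gamma


def _check_beta(beta, data: RegressionData) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.p:
        raise DimensionError(
            f"beta has length {beta.shape[0]}, expected p={data.p}"
        )
    return beta


def esl_loss(t, gamma: float):
    """Phi_gamma(t) = 1 - exp(-t^2/gamma); vectorised over ``t``.

    Symmetric in t, non-decreasing in |t|, with range [0, 1).
    """
    gamma = _check_gamma(gamma)
    t = np.asarray(t, dtype=float)
    out = -np.expm1(-(t**2) / gamma)
    return float(out) if out.ndim == 0 else out


def esl_objective(beta, data: RegressionData, gamma: float) -> float:
    """l_n(beta) = sum_i exp(-r_i^2/gamma); lies in (0, n]."""
    gamma = _check_gamma(gamma)
    beta = _check_beta(beta, data)
    r = data.y - data.X @ beta
    return float(np.exp(-(r**2) / gamma).sum())


def esl_score(beta, data: RegressionData, gamma: float) -> np.ndarray:
    """Gradient of :func:`esl_objective` with respect to beta.

    d l_n / d beta = sum_i (2 r_i / gamma) exp(-r_i^2/gamma) x_i.
    """
    gamma = _check_gamma(gamma)
    beta = _check_beta(beta, data)
    r = data.y - data.X @ beta
    w = np.exp(-(r**2) / gamma)
    return data.X.T @ ((2.0 / gamma) * r * w)


@dataclass
class ESLFit:
    """Result of an exponential-squared-loss fit.

    ``weights`` are the per-observation weights exp(-r_i^2/gamma) at the
    solution; ``objective`` equals their sum.  ``m`` is the size of the
    pseudo-outlier set at the final residuals.  ``trace`` records the
    coefficient step norms of the (inner) IRLS iterations;
    ``outer_trace`` and ``gamma_trace`` are filled by the full
    data-driven pipeline.
    """

    beta: np.ndarray
    gamma: float
    residuals: np.ndarray
    weights: np.ndarray
    objective: float
    m: int
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    objective_trace: list = field(default_factory=list, repr=False)
    n_outer_iters: int = 0
    outer_trace: list = field(default_factory=list)
    gamma_trace: list = field(default_factory=list)


def _irls_step(X: np.ndarray, y: np.ndarray, w: np.ndarray, p: int) -> np.ndarray:
    """One weighted least-squares solve; raises on degenerate weighting."""
    if np.count_nonzero(w > w.max() * 1e-12) < p:
        raise DegenerateFitError(
            "weights concentrated on fewer points than parameters"
        )
    Xw = X * w[:, None]
    A = Xw.T @ X
    b = Xw.T @ y
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:  # exactly singular
        raise DegenerateFitError(f"weighted normal equations singular: {err}")
    if not np.all(np.isfinite(beta)) or np.linalg.cond(A) > 1e12:
        raise DegenerateFitError("weighted design effectively rank deficient")
    return beta


def fit_esl_fixed_gamma(
    data: RegressionData,
    gamma: float,
    beta_init,
    tol: float = 1e-8,
    max_iter: int = 200,
    max_halvings: int = 30,
) -> ESLFit:
    """Maximise l_n(beta) at fixed gamma by IRLS with step halving.

    Each iteration solves the weighted normal equations at the current
    weights and moves toward that solution, halving the step (up to
    ``max_halvings`` times) whenever the raw step would decrease the
    objective, so accepted iterations never decrease it.  Convergence is
    declared when the gradient infinity-norm or the step norm falls
    below ``tol``.
    """
    gamma = _check_gamma(gamma)
    check_full_rank(data.X)
    beta = _check_beta(beta_init, data)
    X, y = data.X, data.y

    r = y - X @ beta
    w = np.exp(-(r**2) / gamma)
    obj = float(w.sum())
    trace: list[float] = []
    obj_trace: list[float] = [obj]
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        grad = X.T @ ((2.0 / gamma) * r * w)
        if np.max(np.abs(grad)) <= tol:
            converged = True
            n_iter -= 1
            break
        target = _irls_step(X, y, w, data.p)
        step = target - beta
        accepted = False
        t = 1.0
        for _ in range(max_halvings + 1):
            cand = beta + t * step
            r_c = y - X @ cand
            w_c = np.exp(-(r_c**2) / gamma)
            obj_c = float(w_c.sum())
            if obj_c >= obj - 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            # no ascent direction left at this resolution: stop here
            break
        delta = float(np.linalg.norm(cand - beta))
        beta, r, w, obj = cand, r_c, w_c, obj_c
        trace.append(delta)
        obj_trace.append(obj)
        if delta <= tol:
            converged = True
            break

    try:
        m = pseudo_outlier_set(r).m
    except InvalidParameterError:
        m = 0
    return ESLFit(
        beta=beta,
        gamma=gamma,
        residuals=r,
        weights=w,
        objective=obj,
        m=m,
        converged=converged,
        n_iter=n_iter,
        trace=trace,
        objective_trace=obj_trace,
    )
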