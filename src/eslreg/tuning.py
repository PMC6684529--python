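"""Data-driven selection of the tuning parameter gamma and the outer
fixed-point loop of the exponential-squared-loss estimator.

One outer iteration, at the current coefficient vector:

1. compute residuals, the robust scale S_n, and the pseudo-outlier set
   (observations with |r_i| >= 2.5 S_n);
2. over a candidate grid, pick the gamma minimising the determinant of
   the estimated asymptotic (sandwich) covariance V(gamma) among
   candidates whose feasibility functional zeta(gamma) lies in (0, 1];
3. re-maximise the objective at that gamma, starting from the current
   coefficients.

The loop starts at the MM estimate and stops when the Euclidean norm of
the coefficient change drops below 1e-2.

The candidate grid is geometric, from S_n^2/50 to 200*S_n^2: gamma
competes with squared residuals inside the exponent, so the natural
scale is the squared robust residual scale.  The sandwich is
V = I1^{-1} Sigma I1^{-1}, with I1 the (negated, separable) mean
curvature of the objective and Sigma the empirical covariance of the
per-observation score contributions (2 r_i/gamma) exp(-r_i^2/gamma) x_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RegressionData, check_full_rank
from .exceptions import (
    InvalidParameterError,
    NoFeasibleGammaError,
)
from .loss import ESLFit, _check_gamma, fit_esl_fixed_gamma
from .mm import MMConfig, fit_mm
from .scale import PseudoOutlierSet, pseudo_outlier_set, residual_scale_sn

__all__ = [
    "AsymptoticCov",
    "FitConfig",
    "zeta",
    "gamma_grid",
    "asymptotic_cov",
    "select_gamma",
    "fit_esl",
]

#: condition-number bound beyond which I1 is treated as singular
COND_LIMIT = 1e12


@dataclass
class AsymptoticCov:
    """Sandwich covariance pieces for one candidate gamma."""

    gamma: float
    I1: np.ndarray
    Sigma: np.ndarray
    V: np.ndarray
    detV: float
    zeta: float
    feasible: bool


def zeta(gamma: float, residuals, outliers: PseudoOutlierSet) -> float:
    """Feasibility functional 2m/n + (2/n) sum over non-outliers of
    Phi_gamma(r_i).  gamma is admissible when this lies in (0, 1]."""
    gamma = _check_gamma(gamma)
    r = np.asarray(residuals, dtype=float).ravel()
    n = r.size
    mask = outliers.mask
    if mask is None:
        mask = np.zeros(n, dtype=bool)
        mask[outliers.indices] = True
    r_in = r[~mask]
    phi = -np.expm1(-(r_in**2) / gamma)
    return 2.0 * outliers.m / n + 2.0 / n * float(phi.sum())


def gamma_grid(residuals, n_points: int = 40,
               lo: float = 1.0 / 50.0, hi: float = 200.0) -> np.ndarray:
    """Geometric candidate grid anchored at the squared robust scale.

    Falls back to the residual standard deviation when S_n = 0 (more
    than half the residuals tied).
    """
    r = np.asarray(residuals, dtype=float).ravel()
    s = residual_scale_sn(r)
    if s <= 0.0:
        s = float(np.std(r))
    if s <= 0.0:
        raise InvalidParameterError(
            "all residuals identical: no scale to anchor the gamma grid"
        )
    return np.geomspace(lo * s**2, hi * s**2, n_points)


def _i1_scalar(r: np.ndarray, gamma: float) -> float:
    """Negated mean curvature scalar: -(1/n) sum (2/g) e^{-r^2/g} (2r^2/g - 1).

    Positive near a maximum, where most residuals satisfy r^2 < gamma/2.
    """
    e = np.exp(-(r**2) / gamma)
    return -float(np.mean((2.0 / gamma) * e * (2.0 * r**2 / gamma - 1.0)))


def _score_matrix(r: np.ndarray, X: np.ndarray, gamma: float) -> np.ndarray:
    """Per-observation score contributions, shape (n, p)."""
    s = (2.0 * r / gamma) * np.exp(-(r**2) / gamma)
    return s[:, None] * X


def asymptotic_cov(beta, data: RegressionData, gamma: float) -> AsymptoticCov:
    """Sandwich covariance V(gamma) = I1^{-1} Sigma I1^{-1} at ``beta``.

    A nearly singular I1 (condition number above 1e12, or non-positive
    curvature scalar) yields ``feasible=False`` with NaN V rather than
    an exception.
    """
    gamma = _check_gamma(gamma)
    check_full_rank(data.X)
    beta = np.asarray(beta, dtype=float).ravel()
    r = data.y - data.X @ beta
    out = pseudo_outlier_set(r)
    z = zeta(gamma, r, out)

    n = data.n
    Mxx = data.X.T @ data.X / n
    a = _i1_scalar(r, gamma)
    I1 = a * Mxx
    S = _score_matrix(r, data.X, gamma)
    Sigma = np.atleast_2d(np.cov(S, rowvar=False, ddof=1))

    feasible = 0.0 < z <= 1.0
    if a <= 0.0 or np.linalg.cond(I1) > COND_LIMIT:
        V = np.full((data.p, data.p), np.nan)
        detV = np.inf
        feasible = False
    else:
        I1_inv = np.linalg.inv(I1)
        V = I1_inv @ Sigma @ I1_inv
        V = 0.5 * (V + V.T)
        sign, logdet = np.linalg.slogdet(Sigma)
        detV = 0.0 if sign <= 0 else float(
            np.exp(logdet - 2.0 * data.p * np.log(a))
            / np.linalg.det(Mxx) ** 2
        )
    return AsymptoticCov(
        gamma=gamma, I1=I1, Sigma=Sigma, V=V, detV=detV, zeta=z,
        feasible=feasible,
    )


def _gamma_table(r: np.ndarray, X: np.ndarray,
                 out: PseudoOutlierSet, grid: np.ndarray):
    """Vectorised (zeta, curvature scalar, log det Sigma) over the grid."""
    n, p = X.shape
    g = grid[:, None]                       # (G, 1)
    r2 = r**2
    E = np.exp(-r2[None, :] / g)            # (G, n)

    mask = out.mask
    if mask is None:
        mask = np.zeros(n, dtype=bool)
        mask[out.indices] = True
    phi_in = (1.0 - E)[:, ~mask]
    zetas = 2.0 * out.m / n + 2.0 / n * phi_in.sum(axis=1)

    a = -np.mean((2.0 / g) * E * (2.0 * r2[None, :] / g - 1.0), axis=1)

    S = (2.0 * r[None, :] / g) * E          # (G, n)
    M1 = (S @ X) / n                        # (G, p)
    raw = np.einsum("gn,ni,nj->gij", S**2, X, X)
    Sigma = (raw - n * M1[:, :, None] * M1[:, None, :]) / (n - 1)
    sign, logdet = np.linalg.slogdet(Sigma)
    return zetas, a, sign, logdet


def select_gamma(beta, data: RegressionData, grid=None) -> float:
    """Minimise det V(gamma) over the feasible grid; ties -> larger gamma.

    Residuals and the pseudo-outlier set are computed once at ``beta``.
    Raises :class:`NoFeasibleGammaError` (carrying the full diagnostic
    table) when no candidate has zeta in (0, 1] and positive curvature.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    r = data.y - data.X @ beta
    out = pseudo_outlier_set(r)
    if grid is None:
        grid = gamma_grid(r)
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0 or np.any(grid <= 0):
        raise InvalidParameterError("grid must be non-empty and positive")

    X = data.X
    n, p = X.shape
    Mxx = X.T @ X / n
    sgn_m, logdet_m = np.linalg.slogdet(Mxx)
    cond_ok = sgn_m > 0 and np.linalg.cond(Mxx) <= COND_LIMIT

    zetas, a, sign_s, logdet_s = _gamma_table(r, X, out, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_detV = np.where(
            sign_s > 0,
            logdet_s - 2.0 * p * np.log(np.clip(a, 1e-300, None))
            - 2.0 * logdet_m,
            -np.inf,  # singular Sigma: det V = 0
        )
    feasible = (zetas > 0.0) & (zetas <= 1.0) & (a > 0.0) & cond_ok

    if not feasible.any():
        with np.errstate(over="ignore"):
            detv = np.where(np.isneginf(log_detV), 0.0, np.exp(log_detV))
        table = pd.DataFrame({
            "gamma": grid, "zeta": zetas, "detV": detv, "feasible": feasible,
        })
        raise NoFeasibleGammaError(
            "no candidate gamma with zeta in (0, 1] and positive "
            "definite curvature", table=table,
        )

    ld = np.where(feasible, log_detV, np.inf)
    best = ld.min()
    ties = np.flatnonzero(ld == best)
    return float(grid[ties].max())


@dataclass
class FitConfig:
    """Configuration of the full data-driven fit.

    ``gamma`` fixes the tuning parameter (skipping selection);
    ``beta_init`` substitutes an externally supplied initial estimate
    for the MM stage.  ``n_restarts`` > 0 adds jittered restarts
    (jitter scale 0.5*S_n per coordinate) to each inner maximisation
    and keeps the best local maximum.
    """

    gamma: float | None = None
    outer_tol: float = 1e-2
    max_outer: int = 50
    inner_tol: float = 1e-8
    inner_max_iter: int = 200
    grid_size: int = 40
    grid_lo: float = 1.0 / 50.0
    grid_hi: float = 200.0
    mm: MMConfig = field(default_factory=MMConfig)
    beta_init: np.ndarray | None = None
    n_restarts: int = 0
    restart_seed: int = 0


def _inner_fit(data, gamma, beta0, config: FitConfig) -> ESLFit:
    fit = fit_esl_fixed_gamma(
        data, gamma, beta0,
        tol=config.inner_tol, max_iter=config.inner_max_iter,
    )
    if config.n_restarts > 0:
        rng = np.random.default_rng(config.restart_seed)
        s = residual_scale_sn(fit.residuals)
        for _ in range(config.n_restarts):
            start = beta0 + 0.5 * s * rng.standard_normal(data.p)
            try:
                alt = fit_esl_fixed_gamma(
                    data, gamma, start,
                    tol=config.inner_tol, max_iter=config.inner_max_iter,
                )
            except Exception:
                continue
            if alt.objective > fit.objective:
                fit = alt
    return fit


def _exact_fit(data: RegressionData, beta: np.ndarray,
               gamma: float) -> ESLFit:
    r = data.y - data.X @ beta
    w = np.exp(-(r**2) / gamma)
    return ESLFit(
        beta=beta, gamma=gamma, residuals=r, weights=w,
        objective=float(w.sum()), m=0, converged=True, n_iter=0,
        n_outer_iters=1, outer_trace=[0.0], gamma_trace=[gamma],
    )


def fit_esl(data: RegressionData, config: FitConfig | None = None) -> ESLFit:
    """Full pipeline: MM start, then alternate gamma selection and
    fixed-gamma maximisation until ||beta_old - beta_new|| < 1e-2."""
    config = config or FitConfig()
    check_full_rank(data.X)
    if config.beta_init is not None:
        beta = np.asarray(config.beta_init, dtype=float).ravel()
    else:
        beta = fit_mm(data, config.mm)

    if config.gamma is not None:
        fit = _inner_fit(data, config.gamma, beta, config)
        fit.n_outer_iters = 1
        fit.outer_trace = [float(np.linalg.norm(fit.beta - beta))]
        fit.gamma_trace = [config.gamma]
        return fit

    y_scale = 1.0 + float(np.max(np.abs(data.y))) if data.n else 1.0
    outer_trace: list[float] = []
    gamma_trace: list[float] = []
    converged = False
    fit: ESLFit | None = None
    n_outer = 0

    for n_outer in range(1, config.max_outer + 1):
        r = data.y - data.X @ beta
        if np.max(np.abs(r)) < 1e-12 * y_scale:
            gamma = gamma_trace[-1] if gamma_trace else 1.0
            fit = _exact_fit(data, beta, gamma)
            fit.n_outer_iters = n_outer
            fit.outer_trace = outer_trace + [0.0]
            fit.gamma_trace = gamma_trace + [gamma]
            return fit
        grid = gamma_grid(r, config.grid_size, config.grid_lo, config.grid_hi)
        gamma = select_gamma(beta, data, grid)
        fit = _inner_fit(data, gamma, beta, config)
        delta = float(np.linalg.norm(fit.beta - beta))
        outer_trace.append(delta)
        gamma_trace.append(gamma)
        beta = fit.beta
        if delta < config.outer_tol:
            converged = True
            break

    fit.converged = converged
    fit.n_outer_iters = n_outer
    fit.outer_trace = outer_trace
    fit.gamma_trace = gamma_trace
    fit.m = pseudo_outlier_set(fit.residuals).m
    return fit
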