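"""MM-estimator of regression, used as the robust initial estimate.

Two stages, both with Tukey's bisquare rho:

1. S-stage: among elemental p-point exact fits drawn by seeded
   subsampling, keep the candidate with the smallest bisquare M-scale
   (tuning c0 = 1.547, consistency b = 0.5, giving 50% breakdown), and
   refine it by a few reweighted least-squares steps that keep the
   scale decreasing.
2. M-stage: IRLS with the bisquare psi at c1 = 4.685 (95% Gaussian
   efficiency), holding the S-scale fixed, started at the S-estimate.

The constants follow standard robust-regression practice; the seed
fully determines the subsample sequence, so identical seeds give
identical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import RegressionData, check_full_rank
from .exceptions import DegenerateFitError, InvalidParameterError

__all__ = ["MMConfig", "fit_mm"]


@dataclass
class MMConfig:
    n_subsamples: int = 500
    bisquare_c0: float = 1.547
    bisquare_c1: float = 4.685
    seed: int = 0
    s_refine_iters: int = 20
    m_step_iters: int = 50

    def __post_init__(self) -> None:
        if self.n_subsamples < 50:
            raise InvalidParameterError("n_subsamples must be >= 50")
        if not (0 < self.bisquare_c0 < self.bisquare_c1):
            raise InvalidParameterError("need 0 < c0 < c1")


def _rho(u: np.ndarray, c: float) -> np.ndarray:
    """Bisquare rho normalised to max 1."""
    v = np.clip(1.0 - (u / c) ** 2, 0.0, None)
    return 1.0 - v**3


def _weights(u: np.ndarray, c: float) -> np.ndarray:
    """psi(u)/u for the bisquare, up to a constant factor."""
    v = np.clip(1.0 - (u / c) ** 2, 0.0, None)
    return v**2


def _mscale(r: np.ndarray, c: float, b: float = 0.5,
            tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve mean(rho(r/s)) = b for s by the standard fixed point."""
    s = float(np.median(np.abs(r))) / 0.6745
    if s == 0.0:
        return 0.0
    for _ in range(max_iter):
        m = float(np.mean(_rho(r / s, c)))
        if abs(m - b) < tol * b:
            break
        s *= np.sqrt(m / b)
    return s


def _mscale_batch(R: np.ndarray, c: float, b: float = 0.5,
                  tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Vectorised M-scale over candidate residual rows (N, n)."""
    s = np.median(np.abs(R), axis=1) / 0.6745
    live = s > 0.0
    for _ in range(max_iter):
        if not live.any():
            break
        m = np.mean(_rho(R[live] / s[live, None], c), axis=1)
        done = np.abs(m - b) < tol * b
        s_live = s[live]
        s_live[~done] *= np.sqrt(m[~done] / b)
        s[live] = s_live
        idx = np.flatnonzero(live)
        live[idx[done]] = False
    return s


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    return np.linalg.solve(Xw.T @ X, Xw.T @ y)


def fit_mm(data: RegressionData, config: MMConfig | None = None) -> np.ndarray:
    """High-breakdown MM regression estimate.

    Requires n > 2p so that elemental subsamples leave a majority of
    observations to judge the scale.
    """
    config = config or MMConfig()
    X, y, n, p = data.X, data.y, data.n, data.p
    if n <= 2 * p:
        raise InvalidParameterError(f"need n > 2p (n={n}, p={p})")
    check_full_rank(X)

    rng = np.random.default_rng(config.seed)
    N = config.n_subsamples
    # N random p-subsets without replacement, vectorised via random keys
    keys = rng.random((N, n))
    idx = np.argpartition(keys, p, axis=1)[:, :p]

    A = X[idx]            # (N, p, p)
    bvec = y[idx]         # (N, p)
    dets = np.linalg.det(A)
    good = np.isfinite(dets) & (np.abs(dets) > 1e-30)
    if not good.any():
        raise DegenerateFitError("all elemental subsamples were singular")
    try:
        betas = np.linalg.solve(A[good], bvec[good][..., None])[..., 0]
    except np.linalg.LinAlgError:
        # fall back to per-candidate least squares
        betas = np.stack([
            np.linalg.lstsq(A[i], bvec[i], rcond=None)[0]
            for i in np.flatnonzero(good)
        ])
    betas = betas[np.all(np.isfinite(betas), axis=1)]
    if betas.shape[0] == 0:
        raise DegenerateFitError("no usable elemental fit")

    R = y[None, :] - betas @ X.T
    scales = _mscale_batch(R, config.bisquare_c0)
    zero = scales == 0.0
    if zero.any():
        # an elemental fit already interpolates a majority: exact fit
        return betas[np.flatnonzero(zero)[0]]

    best = int(np.argmin(scales))
    beta = betas[best]
    s = float(scales[best])

    # S-refinement: reweighted steps accepted only while the scale drops
    r = y - X @ beta
    for _ in range(config.s_refine_iters):
        w = _weights(r / s, config.bisquare_c0)
        if np.count_nonzero(w) < p:
            break
        try:
            beta_new = _wls(X, y, w)
        except np.linalg.LinAlgError:
            break
        r_new = y - X @ beta_new
        s_new = _mscale(r_new, config.bisquare_c0)
        if s_new == 0.0:
            return beta_new
        if s_new >= s * (1.0 - 1e-12):
            break
        beta, r, s = beta_new, r_new, s_new

    # M-stage at fixed scale s, bisquare c1, monotone via step halving
    c1 = config.bisquare_c1
    obj = float(np.mean(_rho(r / s, c1)))
    for _ in range(config.m_step_iters):
        w = _weights(r / s, c1)
        if np.count_nonzero(w) < p:
            break
        try:
            target = _wls(X, y, w)
        except np.linalg.LinAlgError:
            break
        step = target - beta
        t, accepted = 1.0, False
        for _ in range(10):
            cand = beta + t * step
            r_c = y - X @ cand
            obj_c = float(np.mean(_rho(r_c / s, c1)))
            if obj_c <= obj + 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        delta = float(np.linalg.norm(cand - beta))
        beta, r, obj = cand, r_c, obj_c
        if delta <= 1e-10 * (1.0 + float(np.linalg.norm(beta))):
            break
    return beta
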