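"""Percentile-bootstrap confidence intervals for regression coefficients.

Case (pairs) resampling: rows are drawn with replacement, and the full
data-driven fit — including re-selection of the tuning parameter — is
re-run on every resample.  Residual resampling is deliberately avoided:
it assumes the homoscedastic-normal error structure this estimator is
built to escape.

By default resample fits are warm-started at the full-data coefficient
estimate instead of re-running the subsampling MM stage; the pipeline
beyond the starting value is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import RegressionData
from .exceptions import (
    DegenerateFitError,
    ESLError,
    InvalidParameterError,
    NoFeasibleGammaError,
    RankDeficiencyError,
)
from .tuning import FitConfig, fit_esl

__all__ = ["BootstrapResult", "bootstrap_ci", "percentile_interval"]


def percentile_interval(estimates: np.ndarray, level: float):
    """Equal-tailed percentile bounds with type-7 (linear) interpolation.

    ``estimates`` has shape (B, p); returns (lower, upper), each length p.
    """
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(
        estimates, [alpha, 100.0 - alpha], axis=0, method="linear"
    )
    return np.atleast_1d(lo), np.atleast_1d(hi)


@dataclass
class BootstrapResult:
    """Percentile bootstrap summary for one fitted model."""

    B: int
    level: float
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_failed: int
    seed: int
    param_names: list[str]
    estimates: np.ndarray = None

    @property
    def unreliable(self) -> bool:
        """More than 5% of resamples failed to fit."""
        return self.n_failed / self.B > 0.05

    @property
    def excludes_zero(self) -> np.ndarray:
        """Per coefficient: does the interval exclude 0 (significance
        call used with the trial model)?"""
        return (self.lower > 0.0) | (self.upper < 0.0)


def bootstrap_ci(
    data: RegressionData,
    fit_config: FitConfig | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    warm_start: bool = True,
) -> BootstrapResult:
    """Percentile bootstrap CI for every coefficient of the ESL fit.

    Resamples whose fit fails (rank-deficient design after resampling,
    degenerate weighting, or empty feasible gamma set) are skipped and
    counted in ``n_failed``; the result is flagged unreliable when more
    than 5% fail.
    """
    if B < 100:
        raise InvalidParameterError("B must be at least 100")
    if not 0.0 < level < 1.0:
        raise InvalidParameterError("level must be in (0, 1)")
    fit_config = fit_config or FitConfig()

    full_fit = fit_esl(data, fit_config)
    point = full_fit.beta
    if warm_start:
        resample_config = replace(fit_config, beta_init=point)
    else:
        resample_config = fit_config

    rng = np.random.default_rng(seed)
    estimates = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, data.n, data.n)
        sub = data.take(idx)
        try:
            fit = fit_esl(sub, resample_config)
        except (RankDeficiencyError, DegenerateFitError,
                NoFeasibleGammaError, ESLError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        estimates.append(fit.beta)

    est = np.asarray(estimates)
    if est.shape[0] == 0:
        raise DegenerateFitError("every bootstrap resample failed to fit")
    lower, upper = percentile_interval(est, level)
    return BootstrapResult(
        B=B, level=level, point=point, lower=lower, upper=upper,
        n_failed=n_failed, seed=seed,
        param_names=list(data.column_names), estimates=est,
    )
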