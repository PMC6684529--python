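"""Model / Results interface over the exponential-squared-loss pipeline.

Usage mirrors the conventional statistical-modelling shape::

    model = ESLRegression.from_dataframe(df, spec)
    res = model.fit()            # data-driven gamma selection
    print(res.summary())
    ci = res.bootstrap_ci(B=1000, seed=1)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import RegressionData
from .inference import BootstrapResult, bootstrap_ci
from .io import ModelSpec, build_design
from .loss import ESLFit
from .tuning import FitConfig, fit_esl

__all__ = ["ESLRegression", "ESLResults"]


class ESLRegression:
    """Robust linear regression with the exponential squared loss.

    Parameters
    ----------
    endog : array-like, length n
        Outcome vector.
    exog : array-like, (n, p)
        Design matrix including a leading intercept column of ones.
    column_names : list of str, optional
        Labels for the columns of ``exog``.
    """

    def __init__(self, endog, exog, column_names=None):
        self.data = RegressionData(endog, exog, column_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec) -> "ESLRegression":
        """Build the model from a raw table and a column specification."""
        data = build_design(df, spec)
        model = cls.__new__(cls)
        model.data = data
        return model

    @classmethod
    def from_regression_data(cls, data: RegressionData) -> "ESLRegression":
        model = cls.__new__(cls)
        model.data = data
        return model

    @property
    def endog(self) -> np.ndarray:
        return self.data.y

    @property
    def exog(self) -> np.ndarray:
        return self.data.X

    def fit(self, gamma: float | None = None,
            config: FitConfig | None = None) -> "ESLResults":
        """Fit the model.

        With ``gamma=None`` (default) the tuning parameter is selected
        by the data-driven determinant-minimisation loop; a fixed
        ``gamma`` skips selection and maximises the objective once from
        the MM start.
        """
        config = config or FitConfig()
        if gamma is not None:
            from dataclasses import replace
            config = replace(config, gamma=gamma)
        fit = fit_esl(self.data, config)
        return ESLResults(self, fit, config)


class ESLResults:
    """Fitted exponential-squared-loss regression."""

    def __init__(self, model: ESLRegression, fit: ESLFit, config: FitConfig):
        self.model = model
        self._fit = fit
        self.config = config

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.beta, index=self.param_names)

    @property
    def param_names(self) -> list[str]:
        return list(self.model.data.column_names)

    @property
    def gamma(self) -> float:
        return self._fit.gamma

    @property
    def resid(self) -> np.ndarray:
        return self._fit.residuals

    @property
    def weights(self) -> np.ndarray:
        return self._fit.weights

    @property
    def objective(self) -> float:
        return self._fit.objective

    @property
    def m(self) -> int:
        """Pseudo-outlier count at the final fit."""
        return self._fit.m

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_outer_iters(self) -> int:
        return self._fit.n_outer_iters

    @property
    def outer_trace(self) -> list:
        return self._fit.outer_trace

    @property
    def gamma_trace(self) -> list:
        return self._fit.gamma_trace

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.data.y - self.resid

    # -- inference ---------------------------------------------------------
    def bootstrap_ci(self, B: int = 1000, level: float = 0.95,
                     seed: int = 0, warm_start: bool = True) -> BootstrapResult:
        """Percentile-bootstrap confidence intervals for all
        coefficients (case resampling; the pipeline, including gamma
        selection, is re-run on every resample)."""
        return bootstrap_ci(
            self.model.data, self.config, B=B, level=level, seed=seed,
            warm_start=warm_start,
        )

    # -- presentation ------------------------------------------------------
    def summary(self, ci: BootstrapResult | None = None) -> str:
        """Plain-text coefficient table.

        Pass a :class:`BootstrapResult` to add interval columns and
        the excludes-zero significance flag.
        """
        d = self.model.data
        lines = [
            "Exponential-squared-loss regression",
            "=" * 65,
            f"n = {d.n}    p = {d.p}    gamma = {self.gamma:.6g}    "
            f"m (pseudo-outliers) = {self.m}",
            f"converged = {self.converged} "
            f"(outer iterations: {self.n_outer_iters})",
            "-" * 65,
        ]
        if ci is None:
            lines.append(f"{'term':<16}{'estimate':>12}")
            for name, b in zip(self.param_names, self._fit.beta):
                lines.append(f"{name:<16}{b:>12.4f}")
        else:
            lines.append(
                f"{'term':<16}{'estimate':>12}{'lower':>12}{'upper':>12}"
                f"{'excl. 0':>9}"
            )
            for name, b, lo, hi, sig in zip(
                self.param_names, self._fit.beta, ci.lower, ci.upper,
                ci.excludes_zero,
            ):
                lines.append(
                    f"{name:<16}{b:>12.4f}{lo:>12.4f}{hi:>12.4f}"
                    f"{'*' if sig else '':>9}"
                )
            lines.append("-" * 65)
            lines.append(
                f"{int(ci.level * 100)}% percentile bootstrap, "
                f"B = {ci.B}, failed resamples = {ci.n_failed}"
            )
        lines.append("=" * 65)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ESLResults n={self.model.data.n} p={self.model.data.p} "
            f"gamma={self.gamma:.4g} converged={self.converged}>"
        )
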