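"""Monte-Carlo machinery: the contaminated-regression data generator,
an OLS comparator, the replication engine with its Mean/Bias/SD/MSE
summary, error-bar tables, and a synthetic two-arm-trial fixture.

The default :class:`SimulationDesign` is the study's benchmark setting:
n = 300 observations, six independent N(0, 1) continuous covariates and
one uniform 4-level categorical covariate dummy-coded against the last
level, true coefficients (1, 1.2, 1.4, 1.6, 1.8, 2, 2.2, 2.4, 2.6, 2.8)
(intercept first), standard-normal errors on clean rows and Student
t(1) (Cauchy) errors replacing them on a simple-random subset of
exactly round(contamination * n) rows, 100 replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RegressionData, check_full_rank
from .exceptions import DimensionError, ESLError, InvalidParameterError
from .io import CategoricalSpec, ModelSpec, build_design
from .mm import MMConfig
from .tuning import FitConfig, fit_esl

__all__ = [
    "SimulationDesign",
    "ReplicationSummary",
    "simulate_dataset",
    "fit_ols",
    "run_replications",
    "error_bar_summary",
    "mci_like_frame",
    "mci_like_fixture",
]

#: default true coefficient vector (intercept, 6 continuous, 3 dummies)
DEFAULT_BETA = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8)


@dataclass
class SimulationDesign:
    n: int = 300
    beta_true: tuple = DEFAULT_BETA
    n_continuous: int = 6
    n_categories: int = 4
    contamination: float = 0.0
    replications: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        expected = 1 + self.n_continuous + (self.n_categories - 1)
        if self.beta_true.size != expected:
            raise DimensionError(
                f"beta_true must have length {expected}, "
                f"got {self.beta_true.size}"
            )
        if not 0.0 <= self.contamination <= 0.5:
            raise InvalidParameterError(
                "contamination must lie in [0, 0.5]"
            )

    @property
    def p(self) -> int:
        return self.beta_true.size


def simulate_dataset(design: SimulationDesign, seed: int):
    """One replication of the benchmark design.

    Returns ``(RegressionData, mask)`` where ``mask`` marks the rows
    whose error was drawn from t(1) instead of N(0, 1).  Exactly
    round(contamination * n) rows are contaminated, chosen by seeded
    simple random sampling; the heavy-tailed error replaces (does not
    add to) the normal one.
    """
    rng = np.random.default_rng(seed)
    n, k = design.n, design.n_continuous
    Xc = rng.standard_normal((n, k))
    cat = rng.integers(1, design.n_categories + 1, n)
    # dummy-code levels 1..K-1; all-zero row = last category
    Z = np.column_stack([
        (cat == lv).astype(float) for lv in range(1, design.n_categories)
    ])
    X = np.column_stack([np.ones(n), Xc, Z])
    names = (
        ["const"]
        + [f"x{j}" for j in range(1, k + 1)]
        + [f"z{j}" for j in range(1, design.n_categories)]
    )

    eps = rng.standard_normal(n)
    n_bad = int(round(design.contamination * n))
    mask = np.zeros(n, dtype=bool)
    if n_bad > 0:
        bad = rng.choice(n, size=n_bad, replace=False)
        mask[bad] = True
        eps[mask] = rng.standard_t(1, n_bad)
    y = X @ design.beta_true + eps
    return RegressionData(y, X, names), mask


def fit_ols(data: RegressionData) -> np.ndarray:
    """Exact least-squares solution of the normal equations."""
    check_full_rank(data.X)
    beta, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    return beta


@dataclass
class ReplicationSummary:
    """Per-estimator, per-coefficient Mean/Bias/SD/MSE across
    replications.

    ``table`` columns: estimator, term, true, mean, bias, sd, mse.
    Bias = mean - true exactly; SD uses the (R-1) denominator; MSE is
    the average squared error, so mse = bias^2 + sd^2 * (R-1)/R.
    """

    table: pd.DataFrame
    replications: int
    seed: int
    n_failed: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict, repr=False)


def _default_estimators(design: SimulationDesign):
    def esl(data: RegressionData, rep_seed: int) -> np.ndarray:
        cfg = FitConfig(mm=MMConfig(seed=rep_seed))
        return fit_esl(data, cfg).beta

    def ols(data: RegressionData, rep_seed: int) -> np.ndarray:
        return fit_ols(data)

    return {"ESL": esl, "OLS": ols}


def run_replications(
    design: SimulationDesign,
    estimators=None,
) -> ReplicationSummary:
    """Repeat simulate -> fit over ``design.replications`` replications.

    ``estimators`` maps a name to a callable ``f(data, rep_seed)``
    returning a coefficient vector; the default set is {"ESL", "OLS"}.
    Replications where an estimator raises are excluded from its
    summary and counted; more than 10% failures for any estimator is an
    error.
    """
    if design.replications < 2:
        raise InvalidParameterError("need at least 2 replications")
    if estimators is None:
        estimators = _default_estimators(design)

    results = {name: [] for name in estimators}
    n_failed = {name: 0 for name in estimators}
    for r in range(1, design.replications + 1):
        rep_seed = (design.seed + r) % (2**31)
        data, _ = simulate_dataset(design, rep_seed)
        for name, f in estimators.items():
            try:
                beta = np.asarray(f(data, rep_seed), dtype=float)
            except (ESLError, np.linalg.LinAlgError):
                n_failed[name] += 1
                continue
            results[name].append(beta)

    rows = []
    estimates = {}
    for name in estimators:
        est = np.asarray(results[name])
        if n_failed[name] > 0.10 * design.replications:
            raise ESLError(
                f"estimator {name!r} failed on {n_failed[name]} of "
                f"{design.replications} replications"
            )
        estimates[name] = est
        R = est.shape[0]
        mean = est.mean(axis=0)
        bias = mean - design.beta_true
        sd = est.std(axis=0, ddof=1)
        mse = np.mean((est - design.beta_true) ** 2, axis=0)
        for j in range(design.p):
            rows.append({
                "estimator": name,
                "term": f"beta{j}",
                "true": design.beta_true[j],
                "mean": mean[j],
                "bias": bias[j],
                "sd": sd[j],
                "mse": mse[j],
            })
    table = pd.DataFrame(rows)
    return ReplicationSummary(
        table=table, replications=design.replications, seed=design.seed,
        n_failed=n_failed, estimates=estimates,
    )


def error_bar_summary(summary: ReplicationSummary) -> pd.DataFrame:
    """Plot-ready error-bar table: per estimator and coefficient the
    true value, the mean of the estimates, and mean +/- SD."""
    t = summary.table
    out = t[["estimator", "term", "true", "mean", "sd"]].copy()
    out["lower"] = out["mean"] - out["sd"]
    out["upper"] = out["mean"] + out["sd"]
    out["width"] = out["upper"] - out["lower"]
    return out


# ---------------------------------------------------------------------------
# Synthetic two-arm trial fixture
# ---------------------------------------------------------------------------

#: sampling weights of the eight centres (pooled arm sizes of the
#: emulated trial)
_CENTRE_WEIGHTS = np.array([33, 12, 48, 36, 36, 72, 36, 47], dtype=float)

#: generating coefficients of the synthetic trial outcome
_MCI_COEF = {
    "const": 0.24,
    "age": -0.05,
    "bmi": 0.07,
    "ADAS1": 0.31,
    "centre": [1.8, 1.4, -0.5, 0.55, 2.4, 1.5, 0.0],  # centres 1..7 vs 8
    "gender": -0.5,
    "education": 0.4,
    "occupation": -0.25,
    "drug": -0.1,
}


def mci_like_frame(
    n_treatment: int,
    n_control: int,
    seed: int,
    treatment_effect: float = 0.0,
    error_sd: float = 3.3,
    contamination: float = 0.10,
) -> pd.DataFrame:
    """Synthetic stand-in for a two-arm cognitive-impairment trial table.

    Emulates the marginal structure of an eight-centre RCT: age about
    N(63, 8^2), height/weight giving plausible BMI, baseline score
    ADAS1 about N(15, 6^2), binary gender/education/occupation/drug,
    centre frequencies matching the pooled arm sizes, and an outcome
    equal to a linear predictor plus a mixture error (90% normal, 10%
    scaled t(2)) so that residual-normality tests reject.  This is a
    synthetic fixture, not trial data.
    """
    if n_treatment < 20 or n_control < 20:
        raise InvalidParameterError("both arms must have at least 20 subjects")
    rng = np.random.default_rng(seed)
    n = n_treatment + n_control
    group = np.r_[np.ones(n_treatment), np.zeros(n_control)]

    age = rng.normal(63.0, 8.0, n)
    height = rng.normal(164.0, 7.3, n)
    weight = rng.normal(64.5, 9.3, n)
    adas1 = np.clip(rng.normal(15.0, 6.0, n), 1.0, None)
    centre = rng.choice(
        np.arange(1, 9), size=n, p=_CENTRE_WEIGHTS / _CENTRE_WEIGHTS.sum()
    )
    gender = rng.binomial(1, 0.42, n)       # 1 = female
    education = rng.binomial(1, 0.79, n)    # 1 = middle and above
    occupation = rng.binomial(1, 0.73, n)   # 1 = mental
    drug = rng.binomial(1, 0.29, n)         # 1 = prior medication

    bmi = weight / (height / 100.0) ** 2
    centre_eff = np.array(_MCI_COEF["centre"] + [0.0])  # index 1..8
    lin = (
        _MCI_COEF["const"]
        + _MCI_COEF["age"] * age
        + _MCI_COEF["bmi"] * bmi
        + _MCI_COEF["ADAS1"] * adas1
        + centre_eff[centre - 1]
        + treatment_effect * group
        + _MCI_COEF["gender"] * gender
        + _MCI_COEF["education"] * education
        + _MCI_COEF["occupation"] * occupation
        + _MCI_COEF["drug"] * drug
    )
    eps = rng.normal(0.0, error_sd, n)
    n_bad = int(round(contamination * n))
    if n_bad > 0:
        bad = rng.choice(n, size=n_bad, replace=False)
        eps[bad] = error_sd * rng.standard_t(2, n_bad)
    frame = pd.DataFrame({
        "ADASFA": lin + eps,
        "age": age,
        "height": height,
        "weight": weight,
        "ADAS1": adas1,
        "centre": centre,
        "gender": gender,
        "education": education,
        "occupation": occupation,
        "drug": drug,
        "group": group.astype(int),
    })
    return frame


def mci_like_spec() -> ModelSpec:
    """Model specification matching :func:`mci_like_frame`."""
    return ModelSpec(
        outcome="ADASFA",
        continuous=["age", "bmi", "ADAS1"],
        categorical=[
            CategoricalSpec("centre", list(range(1, 9)), 8),
            CategoricalSpec("gender", [1, 0], 0),
            CategoricalSpec("education", [1, 0], 0),
            CategoricalSpec("occupation", [1, 0], 0),
            CategoricalSpec("drug", [1, 0], 0),
        ],
        treatment="group",
        derived={"bmi": "weight / (height / 100) ** 2"},
    )


def mci_like_fixture(
    n_treatment: int,
    n_control: int,
    seed: int,
    **kwargs,
) -> RegressionData:
    """Design-matrix form of :func:`mci_like_frame` (synthetic fixture)."""
    frame = mci_like_frame(n_treatment, n_control, seed, **kwargs)
    return build_design(frame, mci_like_spec())
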