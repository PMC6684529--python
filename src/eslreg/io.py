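"""Data ingestion, categorical encoding, model specification and
results serialisation.

A :class:`ModelSpec` declares which columns of a delimited text file
form the outcome, the continuous covariates, the categorical covariates
(with their level order and reference level), and optionally a binary
treatment-arm indicator.  The design matrix is assembled as: intercept
first, continuous covariates (including any derived ones) next, the
treatment indicator, then the dummy indicators of each categorical
covariate.  The reference level maps to the all-zero dummy row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import RegressionData
from .exceptions import DimensionError, InvalidParameterError

__all__ = [
    "CategoricalSpec",
    "ModelSpec",
    "encode_categorical",
    "read_table",
    "write_fit_results",
    "read_fit_results",
]

logger = logging.getLogger("eslreg")

#: schema version stamped into every JSON result file
RESULTS_SCHEMA_VERSION = 1


@dataclass
class CategoricalSpec:
    name: str
    levels: list
    reference: object

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise InvalidParameterError(
                f"reference level {self.reference!r} not among declared "
                f"levels of {self.name!r}"
            )


@dataclass
class ModelSpec:
    """Declarative description of the regression model columns."""

    outcome: str
    continuous: list[str] = field(default_factory=list)
    categorical: list[CategoricalSpec] = field(default_factory=list)
    treatment: str | None = None
    #: derived columns, name -> pandas eval expression on the raw table
    derived: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categorical = [
            c if isinstance(c, CategoricalSpec) else CategoricalSpec(*c)
            for c in self.categorical
        ]
        names = (
            [self.outcome]
            + list(self.continuous)
            + [c.name for c in self.categorical]
            + ([self.treatment] if self.treatment else [])
        )
        if len(names) != len(set(names)):
            raise InvalidParameterError("a column is listed twice in the spec")

    @property
    def model_columns(self) -> list[str]:
        cols = [self.outcome] + [
            c for c in self.continuous if c not in self.derived
        ]
        if self.treatment:
            cols.append(self.treatment)
        cols += [c.name for c in self.categorical]
        return cols

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        cats = [
            CategoricalSpec(c["name"], list(c["levels"]), c["reference"])
            for c in d.get("categorical", [])
        ]
        return cls(
            outcome=d["outcome"],
            continuous=list(d.get("continuous", [])),
            categorical=cats,
            treatment=d.get("treatment"),
            derived=dict(d.get("derived", {})),
        )


def encode_categorical(values, levels, reference) -> np.ndarray:
    """Dummy-code ``values`` against an ordered level list.

    k levels produce k-1 binary columns, ordered as declared with the
    reference level removed; the reference level maps to an all-zero
    row.  An unseen value is an error naming the offending level.
    """
    levels = list(levels)
    if reference not in levels:
        raise InvalidParameterError(
            f"reference level {reference!r} not in levels"
        )
    values = list(values)
    unseen = sorted({repr(v) for v in values if v not in levels})
    if unseen:
        raise InvalidParameterError(
            f"value(s) {', '.join(unseen)} not among declared levels"
        )
    keep = [lv for lv in levels if lv != reference]
    out = np.zeros((len(values), len(keep)))
    for j, lv in enumerate(keep):
        out[:, j] = [1.0 if v == lv else 0.0 for v in values]
    return out


def build_design(df: pd.DataFrame, spec: ModelSpec) -> RegressionData:
    """Assemble y and X from a (already complete-case) data frame."""
    work = df.copy()
    for name, expr in spec.derived.items():
        work[name] = work.eval(expr)

    y = work[spec.outcome].to_numpy(dtype=float)
    cols = [np.ones(len(work))]
    names = ["const"]
    for c in spec.continuous:
        cols.append(work[c].to_numpy(dtype=float))
        names.append(c)
    if spec.treatment:
        t = work[spec.treatment].to_numpy(dtype=float)
        uniq = np.unique(t)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise InvalidParameterError(
                f"treatment column {spec.treatment!r} is not binary 0/1"
            )
        cols.append(t)
        names.append(spec.treatment)
    X = np.column_stack(cols)
    for cat in spec.categorical:
        dummies = encode_categorical(
            work[cat.name].tolist(), cat.levels, cat.reference
        )
        names += [
            f"{cat.name}[{lv}]" for lv in cat.levels if lv != cat.reference
        ]
        X = np.hstack([X, dummies])
    return RegressionData(y, X, names)


def read_table(path, spec: ModelSpec) -> RegressionData:
    """Read a delimited text file (comma or tab, auto-detected) and
    build the regression problem declared by ``spec``.

    Rows with missing values in any model column are dropped with a
    logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in spec.model_columns if c not in df.columns]
    if missing:
        raise InvalidParameterError(
            f"missing column(s) in {path}: {', '.join(missing)}"
        )
    before = len(df)
    df = df.dropna(subset=spec.model_columns)
    dropped = before - len(df)
    if dropped:
        logger.warning(
            "dropped %d row(s) with missing values in model columns", dropped
        )
    if len(df) == 0:
        raise DimensionError("no complete rows left after filtering")
    return build_design(df, spec)


def _coef_frame(results) -> pd.DataFrame:
    frame = pd.DataFrame({
        "term": results.param_names,
        "estimate": np.asarray(results.params, dtype=float),
    })
    return frame


def write_fit_results(results, base_path, extra: dict | None = None) -> None:
    """Serialise a fitted model to ``<base>.csv`` and ``<base>.json``.

    Floats are written with full precision (%.17g) so a round-trip read
    reproduces the coefficient table bit-exactly.
    """
    base = Path(base_path)
    frame = _coef_frame(results)
    frame.to_csv(base.with_suffix(".csv"), index=False,
                 float_format="%.17g")
    payload = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "params": {t: float(v) for t, v in
                   zip(frame["term"], frame["estimate"])},
    }
    for attr in ("gamma", "m", "converged"):
        if hasattr(results, attr):
            v = getattr(results, attr)
            payload[attr] = v if not isinstance(v, np.generic) else v.item()
    if extra:
        payload.update(extra)
    base.with_suffix(".json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


def read_fit_results(base_path) -> pd.DataFrame:
    """Read back the coefficient table written by write_fit_results.

    ``float_precision="round_trip"`` so that %.17g output reproduces
    the in-memory doubles bit-exactly.
    """
    return pd.read_csv(
        Path(base_path).with_suffix(".csv"), float_precision="round_trip"
    )
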