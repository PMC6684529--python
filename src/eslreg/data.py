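"""Container for a regression problem: outcome vector plus design matrix.

The design matrix carries an explicit leading intercept column of ones;
all fitters in this package operate on that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, RankDeficiencyError

__all__ = ["RegressionData", "check_full_rank"]


@dataclass
class RegressionData:
    """Outcome vector ``y`` (length n) and design matrix ``X`` (n x p).

    The first column of ``X`` is expected to be the intercept column of
    ones when the model includes an intercept (every constructor in this
    package builds it that way).  ``column_names`` labels the columns of
    ``X`` in order.
    """

    y: np.ndarray
    X: np.ndarray
    column_names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise DimensionError("X must be a 2-d array")
        if self.y.shape[0] != self.X.shape[0]:
            raise DimensionError(
                f"y has length {self.y.shape[0]} but X has "
                f"{self.X.shape[0]} rows"
            )
        if self.X.shape[0] <= self.X.shape[1]:
            raise DimensionError(
                f"need more observations than parameters "
                f"(n={self.X.shape[0]}, p={self.X.shape[1]})"
            )
        if self.column_names is None:
            self.column_names = ["const"] + [
                f"x{j}" for j in range(1, self.X.shape[1])
            ]
        else:
            self.column_names = list(self.column_names)
            if len(self.column_names) != self.X.shape[1]:
                raise DimensionError(
                    "column_names length does not match number of columns"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def take(self, indices: np.ndarray) -> "RegressionData":
        """Row subset (used for case resampling)."""
        idx = np.asarray(indices)
        return RegressionData(self.y[idx], self.X[idx], list(self.column_names))


def check_full_rank(X: np.ndarray) -> None:
    """Raise :class:`RankDeficiencyError` unless X has full column rank."""
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank < p={X.shape[1]})"
        )
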