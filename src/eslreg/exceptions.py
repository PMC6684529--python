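"""Exception hierarchy for eslreg."""

from __future__ import annotations


class ESLError(Exception):
    """Base class for all eslreg errors."""


class InvalidParameterError(ESLError, ValueError):
    """A scalar parameter (e.g. the tuning parameter gamma) is out of range."""


class DimensionError(ESLError, ValueError):
    """Shapes of the supplied arrays do not agree."""


class RankDeficiencyError(ESLError, ValueError):
    """The design matrix does not have full column rank."""


class DegenerateFitError(ESLError, RuntimeError):
    """A weighted fit collapsed: effective support smaller than the
    number of parameters (all weight concentrated on < p points)."""


class NoFeasibleGammaError(ESLError, RuntimeError):
    """No candidate tuning parameter satisfies the feasibility constraint
    zeta(gamma) in (0, 1].

    Carries the full diagnostic table of candidates as ``table`` (a
    pandas DataFrame with columns gamma, zeta, detV, feasible).
    """

    def __init__(self, message: str, table=None):
        super().__init__(message)
        self.table = table
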