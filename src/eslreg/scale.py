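"""Robust residual scale and the pseudo-outlier set.

The residual scale is the normalised median absolute deviation
S_n = 1.4826 * median_i |r_i - median_j r_j|, consistent for the error
standard deviation under normality.  Observations whose absolute
residual reaches 2.5 * S_n form the pseudo-outlier set used by the
tuning-parameter selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["PseudoOutlierSet", "residual_scale_sn", "pseudo_outlier_set"]

#: consistency factor making the MAD unbiased for sigma under normality
MAD_CONSTANT = 1.4826

#: number of robust scales an absolute residual must reach to be flagged
OUTLIER_THRESHOLD = 2.5


@dataclass
class PseudoOutlierSet:
    """Result of the outlier screen at a given coefficient vector.

    ``degenerate_scale`` is set when S_n = 0 (more than half of the
    residuals identical), in which case no observation is flagged.
    """

    s_n: float
    indices: np.ndarray
    m: int
    n: int
    degenerate_scale: bool = False
    #: boolean mask, True where the observation is a pseudo-outlier
    mask: np.ndarray = field(default=None, repr=False)


def residual_scale_sn(residuals) -> float:
    """Normalised MAD of a residual vector.

    Uses the midpoint convention of :func:`numpy.median` for even
    counts.  Scale equivariant: S_n(c r) = |c| S_n(r).
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 2:
        raise InvalidParameterError(
            "residual scale needs at least two residuals"
        )
    return MAD_CONSTANT * float(np.median(np.abs(r - np.median(r))))


def pseudo_outlier_set(residuals) -> PseudoOutlierSet:
    """Flag observations with |r_i| >= 2.5 * S_n.

    Flagging is two-sided: the loss is symmetric, so gross negative
    residuals are outliers on the same footing as positive ones.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    s_n = residual_scale_sn(r)
    if s_n == 0.0:
        mask = np.zeros(r.size, dtype=bool)
        return PseudoOutlierSet(
            s_n=0.0,
            indices=np.empty(0, dtype=int),
            m=0,
            n=r.size,
            degenerate_scale=True,
            mask=mask,
        )
    mask = np.abs(r) >= OUTLIER_THRESHOLD * s_n
    idx = np.flatnonzero(mask)
    return PseudoOutlierSet(
        s_n=s_n, indices=idx, m=int(idx.size), n=r.size, mask=mask
    )
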