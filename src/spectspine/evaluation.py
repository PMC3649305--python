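"""Segmentation accuracy metrics and inter-rater reliability.

Automatic masks are scored against a reference mask with volume-fraction
metrics, all normalized by the reference volume ``V(Am)``:

    TP = V(Aa n Am) / V(Am)
    FP = |V(Aa u Am) - V(Am)| / V(Am)
    FN = |V(Aa u Am) - V(Aa)| / V(Am)

so that TP + FN = 1 holds identically, FP = 0 iff Aa is contained in Am
and FN = 0 iff Am is contained in Aa.  Qualitative accept/reject grades
from multiple raters are summarized with Cronbach's alpha,

    alpha = k / (k - 1) * (1 - sum_i s_i^2 / s_T^2),

computed with sample (n-1) variances; here the "items" are the k graded
datasets and the observations are the raters, so s_i^2 is the variance
of item i across raters and s_T^2 the variance of the per-rater totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import DegenerateInputError
from .preprocess import BinaryVolume

__all__ = ["EvalReport", "RaterScores", "volume_fractions",
           "cronbach_alpha", "percent"]


@dataclass(frozen=True)
class EvalReport:
    """TP/FP/FN volume fractions (dimensionless; see :func:`percent`)."""

    tp: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        assert 0 <= self.tp <= 1 and self.fp >= 0 and 0 <= self.fn <= 1

    def as_percent(self) -> tuple[float, float, float]:
        return percent(self.tp), percent(self.fp), percent(self.fn)


@dataclass
class RaterScores:
    """A rater x item score matrix (binary 0/1 in the intended use)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or min(self.scores.shape) < 2:
            raise ValueError("scores must be a matrix with >= 2 raters "
                             "and >= 2 items")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must not contain missing entries")


def percent(fraction: float) -> float:
    """Format a fraction as a percentage, one decimal, rounding half up."""
    return float(Decimal(fraction * 100).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


def volume_fractions(Aa: BinaryVolume, Am: BinaryVolume) -> EvalReport:
    """TP/FP/FN volume fractions of an automatic mask vs a reference.

    Volumes are voxel counts times voxel volume; with matching voxel
    spacings the spacing cancels, so counts are used directly.

    Raises
    ------
    ValueError
        Shape mismatch between the two masks.
    DegenerateInputError
        Empty reference mask.
    """
    if Aa.shape != Am.shape:
        raise ValueError(f"mask shapes differ: {Aa.shape} vs {Am.shape}")
    a = Aa.bits.astype(bool)
    m = Am.bits.astype(bool)
    v_m = int(m.sum())
    if v_m == 0:
        raise DegenerateInputError("reference mask is empty")
    v_a = int(a.sum())
    v_union = int((a | m).sum())
    v_inter = int((a & m).sum())
    return EvalReport(tp=v_inter / v_m,
                      fp=abs(v_union - v_m) / v_m,
                      fn=abs(v_union - v_a) / v_m)


def cronbach_alpha(scores, item_axis: int = 1) -> float:
    """Cronbach's alpha of a rater x item score matrix.

    Parameters
    ----------
    scores
        :class:`RaterScores` or a 2D array.  By default rows are raters
        and columns are items (``item_axis=1``); pass ``item_axis=0``
        for the transposed orientation.
    item_axis
        Which axis indexes the k items whose variances enter the sum.

    Raises
    ------
    DegenerateInputError
        Zero total-score variance, where alpha is undefined.
    """
    if isinstance(scores, RaterScores):
        matrix = scores.scores
    else:
        matrix = RaterScores(np.asarray(scores)).scores
    if item_axis == 0:
        matrix = matrix.T
    elif item_axis != 1:
        raise ValueError("item_axis must be 0 or 1")
    k = matrix.shape[1]
    item_vars = matrix.var(axis=0, ddof=1)
    totals = matrix.sum(axis=1)
    total_var = totals.var(ddof=1)
    if total_var == 0:
        raise DegenerateInputError(
            "total-score variance is zero; alpha is undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
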