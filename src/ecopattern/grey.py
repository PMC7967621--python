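"""Deng-type grey relational analysis with six-level grading.

Grey relational analysis measures how closely each comparison series tracks
a reference series over a (typically short) sequence of observations — well
suited to small-sample ecological time series.  After dimensionless
preprocessing, the relational coefficient at each time point n for
comparison series m is

    ξ(m, n) = (Δmin + ρ·Δmax) / (Δ(m, n) + ρ·Δmax)

where Δ(m, n) = |x0(n) − xm(n)| and Δmin / Δmax are the global minimum and
maximum of Δ over all comparison series and time points.  ρ ∈ (0, 1] is the
resolution coefficient, conventionally 0.5.  The relational degree R(m) is
the arithmetic mean of ξ(m, ·); a series identical to the reference has
R = 1, and ξ is always in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ValidationError

__all__ = [
    "GreyResult",
    "dimensionless_process",
    "grey_coefficients",
    "grey_degree",
    "grade_correlation",
    "grey_relational",
    "GREY_GRADE_BINS",
]

#: lower-inclusive grade bins; top bin closed at 1.0
GREY_GRADE_BINS = (
    (0.00, 0.25, "Very low"),
    (0.25, 0.45, "Low"),
    (0.45, 0.55, "Medium low"),
    (0.55, 0.65, "Medium high"),
    (0.65, 0.85, "High"),
    (0.85, 1.00, "Very high"),
)


@dataclass
class GreyResult:
    """Coefficients ξ (series × time points), degrees R, grades and ranking."""

    coefficients: pd.DataFrame
    rho: float
    degrees: pd.Series | None = None
    grades: pd.Series | None = None
    ranking: pd.Series | None = None


def dimensionless_process(panel: pd.DataFrame, mode: str = "mean") -> pd.DataFrame:
    """Make each column (series) dimensionless.

    "mean": divide by the series mean; "initial": divide by the first value.
    A constant series becomes all ones under either mode; a zero divisor is
    an error.
    """
    if mode not in {"mean", "initial"}:
        raise ValidationError(f"mode must be 'mean' or 'initial', got {mode!r}")
    div = panel.mean(axis=0) if mode == "mean" else panel.iloc[0]
    zero = div[div == 0]
    if len(zero):
        raise ValidationError(
            f"zero {mode} value for series {list(zero.index)}; cannot scale"
        )
    return panel / div


def grey_coefficients(
    reference: pd.Series | np.ndarray,
    comparisons: pd.DataFrame,
    rho: float = 0.5,
) -> GreyResult:
    """Relational coefficients of each comparison series against the reference.

    Series are assumed already dimensionless (see
    :func:`dimensionless_process`).  Δmin and Δmax are global over all
    comparison series and time points.
    """
    if not 0 < rho <= 1:
        raise ValidationError(f"rho must be in (0, 1], got {rho}")
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or len(ref) < 2:
        raise ValidationError("reference series must be 1-D with length >= 2")
    if len(comparisons) != len(ref):
        raise ValidationError(
            f"series length mismatch: reference {len(ref)}, panel {len(comparisons)}"
        )
    delta = (comparisons.astype(float).sub(ref, axis=0)).abs()
    dmin = float(delta.values.min())
    dmax = float(delta.values.max())
    # a Δmax at float-noise level means every series coincides with the
    # reference; without this guard the coefficients would amplify the noise
    tiny = 1e-12 * max(1.0, float(np.abs(ref).max()))
    if dmax <= tiny:
        xi = pd.DataFrame(1.0, index=delta.index, columns=delta.columns)
    else:
        xi = (dmin + rho * dmax) / (delta + rho * dmax)
    return GreyResult(coefficients=xi.T, rho=rho)  # rows = series, cols = time


def grey_degree(result: GreyResult) -> GreyResult:
    """Mean coefficient per series, grade labels and competition ranking.

    R(m) is the arithmetic mean of ξ(m, ·) over time points.  Ranking is
    descending by R; ties share the smaller (better) rank, and the returned
    order is the stable input order.
    """
    R = result.coefficients.mean(axis=1).rename("R")
    ranks = pd.Series(
        stats.rankdata(-R.to_numpy(), method="min").astype(int),
        index=R.index,
        name="rank",
    )
    grades = R.map(grade_correlation).rename("grade")
    result.degrees = R
    result.grades = grades
    result.ranking = ranks
    return result


def grade_correlation(R: float) -> str:
    """Six-level grade label for a relational degree in [0, 1]."""
    if not 0.0 <= R <= 1.0:
        raise ValidationError(f"relational degree must be in [0, 1], got {R}")
    for lo, hi, label in GREY_GRADE_BINS:
        if lo <= R < hi:
            return label
    return GREY_GRADE_BINS[-1][2]  # R == 1.0: top bin closed


def grey_relational(
    panel: pd.DataFrame,
    reference: str,
    rho: float = 0.5,
    mode: str = "mean",
) -> GreyResult:
    """End-to-end analysis of one panel (rows = time points, cols = series).

    The ``reference`` column is the reference series; every other column is
    compared against it after dimensionless processing.
    """
    if reference not in panel.columns:
        raise ValidationError(f"reference series {reference!r} not in panel")
    dl = dimensionless_process(panel, mode=mode)
    comparisons = dl.drop(columns=[reference])
    return grey_degree(grey_coefficients(dl[reference], comparisons, rho=rho))
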