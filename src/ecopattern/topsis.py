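"""Interval-entropy-weight TOPSIS ranking.

Ranks objects (regions or ecosystem types) by relative closeness to the
per-indicator ideal.  Pipeline: interval (min-max) normalization with
polarity applied → entropy weights → weighted matrix r_ij = W_j · z_ij →
ideal best Q+ (column maxima) and worst Q− (column minima) → Euclidean
distances d± of each object to Q± → closeness C = d− / (d+ + d−) ∈ [0, 1]
(1 = at the ideal).  Ties in the final ranking share the better rank
(competition ranking, "1224").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ValidationError
from .weighting import IndicatorPanel, entropy_weights, interval_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "TopsisResult",
    "ideal_solutions",
    "ideal_distances",
    "relative_closeness",
    "rank_objects",
    "run_topsis",
]


@dataclass
class TopsisResult:
    weighted: pd.DataFrame
    q_plus: pd.Series
    q_minus: pd.Series
    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series
    ranks: pd.Series

    def table(self) -> pd.DataFrame:
        """Report layout: D+, D−, closeness C and the sorting result."""
        return pd.DataFrame(
            {
                "Positive Ideal Distance D+": self.d_plus,
                "Negative Ideal Distance D-": self.d_minus,
                "Relative Proximity C": self.closeness,
                "Sorting Result": self.ranks,
            }
        )


def ideal_solutions(weighted: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-indicator best (max) and worst (min) vectors.

    Polarity has already been folded into normalization, so the maximum is
    always best.
    """
    if weighted.empty:
        raise ValidationError("empty weighted matrix")
    return weighted.max(axis=0), weighted.min(axis=0)


def ideal_distances(
    weighted: pd.DataFrame, q_plus: pd.Series, q_minus: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Euclidean distance of each object to the ideal and anti-ideal."""
    if list(weighted.columns) != list(q_plus.index) or list(weighted.columns) != list(
        q_minus.index
    ):
        raise ValidationError("ideal vectors do not match matrix indicators")
    diff_p = weighted.sub(q_plus, axis=1)
    diff_m = weighted.sub(q_minus, axis=1)
    d_plus = np.sqrt((diff_p**2).sum(axis=1)).rename("d_plus")
    d_minus = np.sqrt((diff_m**2).sum(axis=1)).rename("d_minus")
    return d_plus, d_minus


def relative_closeness(d_plus, d_minus):
    """C = d− / (d+ + d−), elementwise on scalars or aligned vectors.

    The degenerate case d+ = d− = 0 (object identical to both ideals, i.e.
    all objects identical on every indicator) is defined as 0.5.
    """
    dp = np.asarray(d_plus, dtype=float)
    dm = np.asarray(d_minus, dtype=float)
    if (dp < 0).any() or (dm < 0).any():
        raise ValidationError("distances must be non-negative")
    denom = dp + dm
    degenerate = denom == 0
    if degenerate.any():
        logger.warning("degenerate TOPSIS object(s) equidistant at 0; closeness = 0.5")
    with np.errstate(invalid="ignore"):
        c = np.where(degenerate, 0.5, dm / np.where(degenerate, 1.0, denom))
    if isinstance(d_plus, pd.Series):
        return pd.Series(c, index=d_plus.index, name="closeness")
    return float(c) if c.ndim == 0 else c


def rank_objects(closeness: pd.Series) -> pd.Series:
    """Competition ranks, 1 = largest closeness; ties share the better rank."""
    ranks = stats.rankdata(-np.asarray(closeness, dtype=float), method="min")
    return pd.Series(ranks.astype(int), index=closeness.index, name="rank")


def run_topsis(panel: IndicatorPanel, floor: float = 0.0) -> TopsisResult:
    """End-to-end TOPSIS on a raw objects × indicators panel."""
    if panel.data.shape[1] < 1:
        raise ValidationError("panel needs at least one indicator")
    norm = interval_normalize(panel, floor=floor)
    weights = entropy_weights(norm)
    weighted = norm.mul(weights, axis=1)
    q_plus, q_minus = ideal_solutions(weighted)
    d_plus, d_minus = ideal_distances(weighted, q_plus, q_minus)
    closeness = relative_closeness(d_plus, d_minus)
    ranks = rank_objects(closeness)
    return TopsisResult(
        weighted=weighted,
        q_plus=q_plus,
        q_minus=q_minus,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=closeness,
        ranks=ranks,
    )
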