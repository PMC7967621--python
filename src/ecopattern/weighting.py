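"""Indicator panels, min-max normalization and entropy weighting.

An :class:`IndicatorPanel` is an observations × indicators table (epochs or
regions on rows) with a per-indicator polarity: "benefit" (larger is better)
or "cost" (smaller is better).  Normalization rescales each column to [0, 1]
with the polarity applied, so downstream stages can always treat larger as
better.  Weights come from the entropy method: an indicator whose normalized
values are spread unevenly across observations carries more information and
gets more weight; a constant indicator carries none and gets weight 0.

`range_normalize` and `interval_normalize` are mathematically identical
min-max scalings kept as separate entry points so the coupling layer and the
ranking layer can be configured independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "IndicatorPanel",
    "range_normalize",
    "interval_normalize",
    "entropy_weights",
]


@dataclass
class IndicatorPanel:
    """Raw observations × indicators values with per-indicator polarity.

    Indicators without an explicit polarity default to "benefit".
    """

    data: pd.DataFrame
    polarity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise ValidationError("panel needs at least 2 observations")
        if self.data.isna().any().any():
            raise ValidationError("panel contains missing values")
        bad = {c: p for c, p in self.polarity.items() if p not in {"benefit", "cost"}}
        if bad:
            raise ValidationError(f"polarity must be benefit|cost, got {bad}")
        unknown = set(self.polarity) - set(self.data.columns)
        if unknown:
            raise ValidationError(f"polarity given for unknown indicators: {unknown}")

    def polarity_of(self, col: str) -> str:
        return self.polarity.get(col, "benefit")

    @classmethod
    def from_csv(
        cls, path: str | Path, polarity: Mapping[str, str] | None = None
    ) -> "IndicatorPanel":
        """Read a panel CSV whose first column is the observation label.

        Labels are kept as text (epoch "2000" stays "2000", not 2000).
        """
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(data=df, polarity=dict(polarity) if polarity else {})


def _minmax(panel: IndicatorPanel, floor: float) -> pd.DataFrame:
    if not 0.0 <= floor < 1.0:
        raise ValidationError(f"floor must be in [0, 1), got {floor}")
    out = {}
    for col in panel.data.columns:
        x = panel.data[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning(
                "indicator %r is constant; normalized to %g (weight will be 0)",
                col, floor,
            )
            out[col] = pd.Series(floor, index=x.index)
            continue
        z = (x - lo) / (hi - lo)
        if panel.polarity_of(col) == "cost":
            z = 1.0 - z
        out[col] = floor + (1.0 - floor) * z
    return pd.DataFrame(out, index=panel.data.index)


def range_normalize(panel: IndicatorPanel, floor: float = 0.0) -> pd.DataFrame:
    """Min-max rescale each indicator to [floor, 1] with polarity applied.

    benefit: (x − min)/(max − min); cost: (max − x)/(max − min).  A constant
    column maps to ``floor`` everywhere with a warning.  The optional
    ``floor`` (e.g. 0.0001) keeps zeros out of downstream logarithms and
    products; default 0.
    """
    return _minmax(panel, floor)


def interval_normalize(panel: IndicatorPanel, floor: float = 0.0) -> pd.DataFrame:
    """Interval (min-max) scaling used by the ranking layer; see
    :func:`range_normalize` — identical mathematics, independent entry point."""
    return _minmax(panel, floor)


def entropy_weights(norm: pd.DataFrame) -> pd.Series:
    """Shannon-entropy weights from a normalized (non-negative) panel.

    p_ij = x_ij / Σ_i x_ij;  e_j = −(1/ln n) Σ_i p_ij ln p_ij  (0·ln 0 ≡ 0);
    d_j = 1 − e_j;  W_j = d_j / Σ_j d_j.  A column summing to zero gets
    weight 0; if every divergence d_j is 0 (all indicators constant) the
    weights fall back to equal, with a warning.
    """
    x = norm.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("entropy weighting requires non-negative values")
    n, m = x.shape
    if n < 2:
        raise ValidationError("entropy weighting needs at least 2 observations")
    colsum = x.sum(axis=0)
    d = np.zeros(m)
    for j in range(m):
        if colsum[j] <= 0:
            continue  # d stays 0 → weight 0
        p = x[:, j] / colsum[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum() / np.log(n)
        d[j] = 1.0 - e
    if d.sum() <= 0:
        logger.warning("all indicators uninformative; falling back to equal weights")
        w = np.full(m, 1.0 / m)
    else:
        w = d / d.sum()
    return pd.Series(w, index=norm.columns, name="weight")
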