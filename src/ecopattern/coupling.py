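"""Coupling–coordination diagnosis between two subsystems.

The two subsystems here are ecosystem composition (class areas) and
landscape pattern (NP, PD, LPI, MPS of a focal class), each collapsed per
epoch into an entropy-weighted composite value U ∈ [0, 1].  Three quantities
describe their joint state:

* coupling degree      C = n·[Π U / (Σ U)^n]^(1/n)   — 1 when all subsystem
  values are equal and positive, 0 when any vanishes; for n = 2 this is
  2·√(U1·U2)/(U1 + U2);
* coordination index   T = Σ β·U  — the β-weighted mean level;
* coordination degree  D = √(C·T) — the graded headline number.  The plain
  product C·T is also available (model_form "literal") but systematically
  understates D relative to the ten-level grading scheme, so the square-root
  ("modified") form is the default.

D is graded into ten half-open bins of width 0.1 (level 1 "Extreme
imbalance" … level 10 "Best coordination").  The relative priority
P = U_eco / U_land diagnoses which subsystem drives the change: P < 1 means
the ecosystem lags the landscape pattern, P within [1, 100] synchronous
development, larger P an ecosystem lead (thresholds configurable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import ValidationError
from .weighting import IndicatorPanel, entropy_weights, range_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "COORDINATION_LEVELS",
    "composite_value",
    "coupling_degree",
    "coordination_degree",
    "grade_coordination",
    "relative_priority",
    "couple_subsystems",
]

COORDINATION_LEVELS = (
    "Extreme imbalance",
    "Serious imbalance",
    "Moderate imbalance",
    "Mild imbalance",
    "Near imbalance",
    "Barely coordination",
    "Primary coordination",
    "Moderate coordination",
    "Good coordination",
    "Best coordination",
)


def composite_value(norm_panel: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted-sum composite U per observation from a normalized panel."""
    if set(norm_panel.columns) != set(weights.index):
        raise ValidationError("weights do not match panel indicators")
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValidationError(f"weights sum to {weights.sum()}, expected 1")
    vals = norm_panel.to_numpy(dtype=float)
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ValidationError("panel must be normalized to [0, 1]")
    U = norm_panel.mul(weights.reindex(norm_panel.columns), axis=1).sum(axis=1)
    return U.clip(0.0, 1.0).rename("U")


def coupling_degree(U: Sequence[float]) -> float:
    """C = n·[Π U / (Σ U)^n]^(1/n) for n subsystem values in [0, ∞).

    C ∈ [0, 1]; C = 1 iff all values are equal and positive; C = 0 when any
    value is 0.  All-zero input is degenerate and returns 0 with a warning.
    """
    u = np.asarray(list(U), dtype=float)
    if u.ndim != 1 or len(u) < 2:
        raise ValidationError("need at least two subsystem values")
    if (u < 0).any():
        raise ValidationError("subsystem values must be non-negative")
    s = u.sum()
    if s == 0:
        logger.warning("all subsystem values are 0; coupling degree set to 0")
        return 0.0
    n = len(u)
    # geometric form, computed in logs where possible for stability
    if (u == 0).any():
        return 0.0
    log_c = math.log(n) + (np.log(u).sum() - n * math.log(s)) / n
    return float(min(1.0, math.exp(log_c)))


def coordination_degree(
    C: float,
    U: Sequence[float],
    beta: Sequence[float] | None = None,
    model_form: str = "sqrt",
) -> tuple[float, float]:
    """Coordination index T = Σ β·U and coordination degree D.

    model_form "sqrt" (default): D = √(C·T); "literal": D = C·T.
    β defaults to equal weights and must sum to 1.
    """
    u = np.asarray(list(U), dtype=float)
    b = (
        np.full(len(u), 1.0 / len(u))
        if beta is None
        else np.asarray(list(beta), dtype=float)
    )
    if len(b) != len(u):
        raise ValidationError("beta length must match subsystem count")
    if (b < 0).any() or abs(b.sum() - 1.0) > 1e-9:
        raise ValidationError("beta must be non-negative and sum to 1")
    T = float(b @ u)
    D = combine_coupling(C, T, model_form)
    return T, D


def combine_coupling(C: float, T: float, model_form: str = "sqrt") -> float:
    """D from an already-known (C, T) pair under the chosen model form."""
    if not 0.0 <= C <= 1.0:
        raise ValidationError(f"C must be in [0, 1], got {C}")
    if not 0.0 <= T <= 1.0:
        raise ValidationError(f"T must be in [0, 1], got {T}")
    if model_form == "sqrt":
        return math.sqrt(C * T)
    if model_form == "literal":
        return C * T
    raise ValidationError(f"model_form must be 'sqrt' or 'literal', got {model_form!r}")


def grade_coordination(D: float) -> tuple[int, str]:
    """Ten-level grade for D ∈ [0, 1]: bins of width 0.1, lower-inclusive,
    with D = 1 mapped into the top level."""
    if not 0.0 <= D <= 1.0:
        raise ValidationError(f"D must be in [0, 1], got {D}")
    # tiny epsilon guards bin edges against float representation (0.7*10 etc.)
    level = min(int(math.floor(D * 10 + 1e-9)) + 1, 10)
    return level, COORDINATION_LEVELS[level - 1]


def relative_priority(
    U_eco: float,
    U_land: float,
    thresholds: tuple[float, float] = (1.0, 100.0),
) -> tuple[float, str]:
    """Priority ratio P = U_eco / U_land and its development status.

    P below the lower threshold: the ecosystem composite lags the landscape
    pattern ("lag"); between the thresholds (inclusive): "synchronous";
    above the upper: "lead".
    """
    if U_land <= 0:
        raise ValidationError("landscape composite must be positive")
    if U_eco < 0:
        raise ValidationError("ecosystem composite must be non-negative")
    lo, hi = thresholds
    if not 0 < lo <= hi:
        raise ValidationError(f"invalid priority thresholds {thresholds}")
    P = U_eco / U_land
    status = "lag" if P < lo else ("synchronous" if P <= hi else "lead")
    return P, status


def couple_subsystems(
    eco_panel: IndicatorPanel,
    land_panel: IndicatorPanel,
    beta: tuple[float, float] = (0.5, 0.5),
    model_form: str = "sqrt",
    priority_thresholds: tuple[float, float] = (1.0, 100.0),
    floor: float = 0.0,
) -> pd.DataFrame:
    """Full per-epoch coupling–coordination table for two subsystems.

    Each panel is range-normalized and entropy-weighted independently, then
    per epoch: composites (U_eco, U_land) → C → (T, D) → level/label →
    relative priority.  Rows of the two panels must share epoch labels.
    """
    if list(eco_panel.data.index) != list(land_panel.data.index):
        raise ValidationError("subsystem panels must share identical epoch labels")
    records = []
    composites = {}
    for name, panel in (("eco", eco_panel), ("land", land_panel)):
        norm = range_normalize(panel, floor=floor)
        w = entropy_weights(norm)
        composites[name] = composite_value(norm, w)
    for epoch in eco_panel.data.index:
        u_eco = float(composites["eco"].loc[epoch])
        u_land = float(composites["land"].loc[epoch])
        C = coupling_degree([u_eco, u_land])
        T, D = coordination_degree(C, [u_eco, u_land], beta, model_form)
        level, label = grade_coordination(D)
        if u_land > 0:
            P, status = relative_priority(u_eco, u_land, priority_thresholds)
        else:
            P, status = np.nan, "undefined"
        records.append(
            {
                "epoch": epoch,
                "U_eco": u_eco,
                "U_land": u_land,
                "C": C,
                "T": T,
                "D": D,
                "level": level,
                "label": label,
                "priority": P,
                "status": status,
            }
        )
    return pd.DataFrame.from_records(records).set_index("epoch")
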