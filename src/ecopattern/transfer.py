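"""Inter-class area transfer matrices between two epochs.

The transfer matrix A has A[i][j] = area (km²) of cells that are class i at
the first epoch and class j at the second; the diagonal is the unchanged
area.  Row totals are therefore first-epoch class areas and column totals
second-epoch class areas.  Derived change statistics:

* loss  (a class's "roll-out" area) = row total − diagonal
* gain  (a class's "roll-in" area)  = column total − diagonal
* total change = Σ losses = Σ gains = grand total − trace
* roll-out % / roll-in % = 100 · loss (gain) / total change — both
  percentage columns share the single all-class total-change denominator,
  so each sums to 100 across classes.

Reports can restrict the displayed classes (e.g. hide an "other-unused"
class) while totals and the change denominator always keep every class.
The published-report layout puts the *destination* epoch on rows, so the
report writer emits Aᵀ with the gain statistics alongside rows and the loss
statistics along the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import ClassGrid, ValidationError, check_coregistered

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "TransferMatrix",
    "compute_transfer",
    "summarize_change",
    "transfer_to_table",
    "matrix_from_report_layout",
]


@dataclass
class TransferMatrix:
    """k×k area matrix (km²), rows = origin classes, columns = destinations."""

    A: pd.DataFrame
    epoch_from: str = ""
    epoch_to: str = ""

    def __post_init__(self) -> None:
        if (self.A.values < -1e-12).any():
            raise ValidationError("transfer areas must be non-negative")
        if list(self.A.index) != list(self.A.columns):
            raise ValidationError("matrix must have identical row/column class order")

    @property
    def classes(self) -> list[str]:
        return list(self.A.index)

    @property
    def row_totals(self) -> pd.Series:
        return self.A.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.A.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.A.values.sum())

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.A.values), index=self.A.index)

    def transpose(self) -> "TransferMatrix":
        return TransferMatrix(self.A.T, epoch_from=self.epoch_to, epoch_to=self.epoch_from)


def compute_transfer(a: ClassGrid, b: ClassGrid) -> TransferMatrix:
    """Cross-tabulate two co-registered epochs into an area matrix (km²).

    Cells that are nodata in either epoch are excluded from every entry and
    total (intersection analysis); the dropped area is logged.
    """
    if not check_coregistered(a, b):
        raise ValidationError("grids are not co-registered")
    if a.legend.entries != b.legend.entries:
        raise ValidationError("grids use different legends")
    valid = a.valid_mask & b.valid_mask
    dropped = int(a.values.size - valid.sum())
    if dropped:
        logger.info(
            "compute_transfer: dropped %d cells (%.4f km²) nodata in either epoch",
            dropped,
            dropped * a.cell_area_m2 / 1e6,
        )
    codes = list(a.legend.codes)
    code_pos = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    ia = np.vectorize(code_pos.get, otypes=[np.int64])(a.values[valid])
    ib = np.vectorize(code_pos.get, otypes=[np.int64])(b.values[valid])
    counts = np.bincount(ia * k + ib, minlength=k * k).reshape(k, k)
    km2 = counts * (a.cell_area_m2 / 1e6)
    names = [a.legend.name_of(c) for c in codes]
    return TransferMatrix(
        A=pd.DataFrame(km2, index=names, columns=names),
        epoch_from=a.epoch_label,
        epoch_to=b.epoch_label,
    )


def summarize_change(
    T: TransferMatrix, display_classes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-class loss/gain areas and roll-out/roll-in percentages.

    total_change (stored in ``.attrs``) and both percentage denominators
    include every class in the matrix even when ``display_classes`` hides
    some from the returned rows.  When nothing changed the percentage
    columns are NaN.
    """
    if display_classes is not None:
        missing = set(display_classes) - set(T.classes)
        if missing:
            raise ValidationError(f"display classes not in matrix: {sorted(missing)}")
    loss = T.row_totals - T.diagonal
    gain = T.col_totals - T.diagonal
    total_change = float(loss.sum())
    if total_change > 0:
        roll_out = 100.0 * loss / total_change
        roll_in = 100.0 * gain / total_change
    else:
        logger.warning("summarize_change: no change between epochs")
        roll_out = pd.Series(np.nan, index=T.A.index)
        roll_in = pd.Series(np.nan, index=T.A.index)
    out = pd.DataFrame(
        {
            "loss_km2": loss,
            "gain_km2": gain,
            "net_km2": gain - loss,
            "roll_out_pct": roll_out,
            "roll_in_pct": roll_in,
        }
    )
    if display_classes is not None:
        out = out.loc[list(display_classes)]
    out.attrs["total_change_km2"] = total_change
    out.attrs["grand_total_km2"] = T.grand_total
    return out


def transfer_to_table(
    T: TransferMatrix,
    display_classes: Sequence[str] | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Render the report layout: destination classes on rows.

    Columns: one per displayed origin class, then Total (destination-epoch
    class area), Change (gain) and Roll-In (%).  Bottom rows: Total
    (origin-epoch class areas), Change (losses) and Roll-Out (%).  Totals
    and the shared change denominator include hidden classes.
    """
    disp = list(display_classes) if display_classes is not None else T.classes
    summary = summarize_change(T)
    body = T.A.T.loc[disp, disp].round(decimals)  # rows = destination
    body["Total"] = T.col_totals.loc[disp].round(decimals)
    body["Change"] = summary["gain_km2"].loc[disp].round(decimals)
    body["Roll-In (%)"] = summary["roll_in_pct"].loc[disp].round(decimals)

    total_row = pd.Series(np.nan, index=body.columns, name="Total")
    total_row[disp] = T.row_totals.loc[disp].round(decimals)
    total_row["Total"] = round(T.grand_total, decimals)
    change_row = pd.Series(np.nan, index=body.columns, name="Change")
    change_row[disp] = summary["loss_km2"].loc[disp].round(decimals)
    change_row["Change"] = round(summary.attrs["total_change_km2"], decimals)
    rollout_row = pd.Series(np.nan, index=body.columns, name="Roll-Out (%)")
    rollout_row[disp] = summary["roll_out_pct"].loc[disp].round(decimals)
    if summary["roll_out_pct"].notna().any():
        rollout_row["Roll-In (%)"] = 100.0

    out = pd.concat([body, total_row.to_frame().T, change_row.to_frame().T,
                     rollout_row.to_frame().T])
    out.index.name = "Type"
    out.attrs["epoch_from"] = T.epoch_from
    out.attrs["epoch_to"] = T.epoch_to
    return out


def matrix_from_report_layout(
    block: pd.DataFrame, epoch_from: str = "", epoch_to: str = ""
) -> TransferMatrix:
    """Build a TransferMatrix from a report-style k×k block.

    The block must be the bare class-by-class area matrix in report
    orientation (rows = destination classes, columns = origin classes);
    missing cells are treated as 0.
    """
    A = block.T.fillna(0.0).astype(float)  # back to rows = origin
    return TransferMatrix(A=A, epoch_from=epoch_from, epoch_to=epoch_to)


def matrix_from_printed_table(
    block: pd.DataFrame,
    total_col: pd.Series,
    total_row: pd.Series,
    grand_total: float,
    hidden_class: str = "other-unused",
    epoch_from: str = "",
    epoch_to: str = "",
) -> TransferMatrix:
    """Reconstruct a full matrix from a report table whose totals include a
    class hidden from the displayed block.

    ``block`` is the displayed k×k block in report orientation (rows =
    destination, columns = origin); ``total_col`` the printed per-row Total
    column (destination-epoch areas), ``total_row`` the printed bottom Total
    row (origin-epoch areas).  The hidden class's row, column and diagonal
    are recovered by difference; tiny negative residuals from 2-decimal
    rounding are clamped to zero.
    """
    disp = list(block.index)
    A = block.T.astype(float)  # canonical: rows = origin
    hidden_to = (total_col.loc[disp] - block.sum(axis=1)).clip(lower=0.0)
    hidden_from = (total_row.loc[disp] - block.sum(axis=0)).clip(lower=0.0)
    hidden_diag = max(
        0.0,
        grand_total - float(block.values.sum()) - float(hidden_to.sum())
        - float(hidden_from.sum()),
    )
    full = pd.DataFrame(
        0.0, index=disp + [hidden_class], columns=disp + [hidden_class]
    )
    full.loc[disp, disp] = A.values
    full.loc[hidden_class, disp] = hidden_to.values  # hidden origin → displayed dest
    full.loc[disp, hidden_class] = hidden_from.values
    full.loc[hidden_class, hidden_class] = hidden_diag
    return TransferMatrix(A=full, epoch_from=epoch_from, epoch_to=epoch_to)


def write_transfer_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)


def write_transfer_xlsx(table: pd.DataFrame, path: str | Path) -> None:
    table.to_excel(path)
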