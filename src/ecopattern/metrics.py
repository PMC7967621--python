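"""Class-level landscape pattern indices from first principles.

Six class-level indices computed by patch labeling (connected components of
same-class cells):

==========  =============================================  =========
index       definition                                     unit
==========  =============================================  =========
CA          total class area                               ha
NP          number of patches                              count
PD          NP per unit of total landscape area            /100 ha
PLAND       100 · CA / total landscape area                %
LPI         100 · largest patch area / total landscape     %
MPS         CA / NP (absent when NP = 0)                   ha
==========  =============================================  =========

"Total landscape area" is the non-nodata area.  Default connectivity is
8 (queen), the FRAGSTATS default; 4 (rook) is available.  The PD unit is
configurable (``per_100ha`` default, ``per_ha``, ``per_km2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClassGrid, ValidationError

__all__ = [
    "PatchLabeling",
    "label_patches",
    "compute_class_metrics",
    "metrics_delta",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["CA", "NP", "PD", "PLAND", "LPI", "MPS"]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}

_PD_DIVISORS_HA = {"per_100ha": 100.0, "per_ha": 1.0, "per_km2": 100.0}
# per_km2 uses the same divisor as per_100ha because 1 km² = 100 ha


@dataclass
class PatchLabeling:
    """Connected-component labeling of a grid, all classes together.

    ``labels`` assigns every non-nodata cell a positive patch id (0 =
    nodata); ``patch_class`` maps each id to its class code.  Within one
    class the ids partition that class's cells; no id spans two classes.
    """

    labels: np.ndarray
    patch_class: dict[int, int]
    connectivity: int
    patch_cells: dict[int, int]  # id -> cell count

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)


def label_patches(grid: ClassGrid, connectivity: int = 8) -> PatchLabeling:
    """Label maximal same-class connected components.

    Each class is labeled independently with :func:`scipy.ndimage.label`
    under the requested connectivity, and labels are offset so they are
    unique across classes.
    """
    if connectivity not in _STRUCTURES:
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = _STRUCTURES[connectivity]
    labels = np.zeros(grid.shape, dtype=np.int64)
    patch_class: dict[int, int] = {}
    patch_cells: dict[int, int] = {}
    offset = 0
    present = [c for c in grid.legend.codes if np.any(grid.values == c)]
    for code in present:
        mask = grid.values == code
        lab, n = ndimage.label(mask, structure=structure)
        labels[mask] = lab[mask] + offset
        counts = np.bincount(lab[mask])  # index 0 unused
        for i in range(1, n + 1):
            patch_class[offset + i] = code
            patch_cells[offset + i] = int(counts[i])
        offset += n
    return PatchLabeling(
        labels=labels,
        patch_class=patch_class,
        connectivity=connectivity,
        patch_cells=patch_cells,
    )


def compute_class_metrics(
    grid: ClassGrid,
    labeling: PatchLabeling | None = None,
    connectivity: int = 8,
    pd_unit: str = "per_100ha",
) -> pd.DataFrame:
    """Per-class CA, NP, PD, PLAND, LPI, MPS for one epoch.

    Returns a DataFrame indexed by class name with the six metric columns;
    classes present in the legend but absent from the grid get zero area and
    NaN MPS.  The total landscape area (ha) is stored in ``.attrs``.
    """
    if pd_unit not in _PD_DIVISORS_HA:
        raise ValidationError(f"pd_unit must be one of {sorted(_PD_DIVISORS_HA)}")
    if labeling is None:
        labeling = label_patches(grid, connectivity)
    if labeling.labels.shape != grid.shape:
        raise ValidationError("labeling does not match grid shape")

    cell_ha = grid.cell_area_m2 / 1e4
    total_ha = grid.total_area_m2() / 1e4
    if total_ha <= 0:
        raise ValidationError("grid has no valid (non-nodata) area")
    pd_divisor = total_ha / _PD_DIVISORS_HA[pd_unit]  # landscape size in PD units

    rows = {}
    for code in grid.legend.codes:
        name = grid.legend.name_of(code)
        cells = int((grid.values == code).sum())
        ca = cells * cell_ha
        sizes = [n for pid, n in labeling.patch_cells.items()
                 if labeling.patch_class[pid] == code]
        np_ = len(sizes)
        largest_ha = max(sizes) * cell_ha if sizes else 0.0
        rows[name] = {
            "CA": ca,
            "NP": np_,
            "PD": np_ / pd_divisor,
            "PLAND": 100.0 * ca / total_ha,
            "LPI": 100.0 * largest_ha / total_ha,
            "MPS": ca / np_ if np_ > 0 else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")[METRIC_COLUMNS]
    out.index.name = "class"
    out.attrs["total_landscape_area_ha"] = total_ha
    out.attrs["epoch_label"] = grid.epoch_label
    out.attrs["pd_unit"] = pd_unit
    out.attrs["connectivity"] = labeling.connectivity
    return out


def metrics_delta(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Signed per-class metric differences, after − before, same units.

    MPS deltas involving an absent class (NP = 0 on either side) are NaN.
    """
    if set(before.index) != set(after.index):
        raise ValidationError(
            f"class sets differ: {sorted(before.index)} vs {sorted(after.index)}"
        )
    return after.loc[before.index] - before
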