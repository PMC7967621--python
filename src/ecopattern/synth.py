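"""Seeded synthetic landscapes and epoch-to-epoch land-cover change.

Real classified land-cover rasters are rarely redistributable, so every
stage of the pipeline must be exercisable on generated data.  The generator
here is a neutral-landscape construction: a Gaussian-smoothed random field
is thresholded at the quantiles of the target class proportions, which gives
seeded, reproducible multi-class maps whose mean patch size grows with the
smoothing radius.  Epoch-to-epoch change is a per-cell Markov draw from a
specified class-transition probability matrix, either spatially independent
("iid") or concentrated at patch boundaries ("frontier", emulating change
fronts such as disturbance spreading inward from class edges).

Nothing here is calibrated to any real region; the point is controllable
structure, exact seeding and known transition rates for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ClassGrid, Legend, ValidationError

__all__ = ["LandscapeSpec", "TransitionSpec", "generate_landscape", "evolve_landscape"]


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic epoch.

    class_proportions map class names (must exist in the legend) to target
    areal fractions; they must be non-negative and sum to 1.  patch_scale is
    the Gaussian smoothing radius in cells — 0 gives salt-and-pepper noise,
    larger values give larger, rounder patches.
    """

    shape: tuple[int, int]
    class_proportions: dict[str, float]
    cell_size_m: float = 100.0
    patch_scale: float = 3.0
    seed: int = 0
    legend: Legend = field(default_factory=Legend.default)

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValidationError("class proportions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, expected 1")
        if self.patch_scale < 0:
            raise ValidationError("patch_scale must be >= 0")
        for name in self.class_proportions:
            self.legend.code_of(name)  # raises KeyError on unknown class


@dataclass
class TransitionSpec:
    """Per-epoch class-transition probabilities.

    rate_matrix[i][j] is the probability that a cell of class ``classes[i]``
    becomes ``classes[j]`` over one epoch; every row must be a probability
    vector.  spatial_mode "iid" draws each cell independently; "frontier"
    places the changing cells of each class preferentially at that class's
    patch boundaries, so change appears spatially clustered.
    """

    classes: tuple[str, ...]
    rate_matrix: np.ndarray
    spatial_mode: str = "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        k = len(self.classes)
        if self.rate_matrix.shape != (k, k):
            raise ValidationError(
                f"rate_matrix shape {self.rate_matrix.shape} != ({k}, {k})"
            )
        if np.any(self.rate_matrix < 0) or np.any(
            np.abs(self.rate_matrix.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValidationError("each rate_matrix row must be a probability vector")
        if self.spatial_mode not in {"iid", "frontier"}:
            raise ValidationError(f"unknown spatial_mode {self.spatial_mode!r}")


def generate_landscape(spec: LandscapeSpec) -> ClassGrid:
    """Generate a seeded multi-class raster with tunable patch structure.

    A standard-normal field is smoothed with a Gaussian kernel of radius
    ``patch_scale`` and cut at the empirical quantiles matching the
    cumulative class proportions, so realized proportions are exact to
    within one cell.  Classes are assigned in legend order along the field's
    value axis (adjacent classes share boundaries; irrelevant for the
    metrics, which are per class).
    """
    rng = np.random.default_rng(spec.seed)
    field_ = rng.standard_normal(spec.shape)
    if spec.patch_scale > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=spec.patch_scale)

    names = [n for n in spec.legend.names if spec.class_proportions.get(n, 0.0) > 0]
    props = np.array([spec.class_proportions[n] for n in names])
    # rank cells and slice the ranking into proportion-sized blocks: exact
    # proportions, no quantile-tie ambiguity
    order = np.argsort(field_, axis=None, kind="stable")
    n_cells = field_.size
    bounds = np.floor(np.cumsum(props) * n_cells + 0.5).astype(int)
    bounds[-1] = n_cells
    flat = np.empty(n_cells, dtype=np.int64)
    start = 0
    for name, stop in zip(names, bounds):
        flat[order[start:stop]] = spec.legend.code_of(name)
        start = stop
    return ClassGrid(
        values=flat.reshape(spec.shape),
        cell_size_m=spec.cell_size_m,
        legend=spec.legend,
        epoch_label="synthetic",
    )


def _boundary_mask(values: np.ndarray, nodata: int) -> np.ndarray:
    """Cells having at least one 4-neighbour of a different (valid) class."""
    mask = np.zeros(values.shape, dtype=bool)
    valid = values != nodata
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(values, shift, axis=axis)
        rolled_valid = np.roll(valid, shift, axis=axis)
        edge = (values != rolled) & valid & rolled_valid
        # np.roll wraps; mask out the wrapped border row/col
        idx = [slice(None), slice(None)]
        idx[axis] = 0 if shift == 1 else -1
        edge[tuple(idx)] = False
        mask |= edge
    return mask


def evolve_landscape(grid: ClassGrid, spec: TransitionSpec) -> ClassGrid:
    """Apply one epoch of class transitions to a grid.

    Nodata cells never change, so the non-nodata cell count is conserved.
    In "iid" mode each cell's next class is an independent categorical draw
    from its class's rate_matrix row.  In "frontier" mode the number of
    cells of class i moving to class j is the same binomial-expected count,
    but the moving cells are picked from class-boundary cells first, producing
    spatially clustered change.
    """
    codes = {name: grid.legend.code_of(name) for name in spec.classes}
    present = set(np.unique(grid.values).tolist()) - {grid.nodata_code}
    uncovered = present - set(codes.values())
    if uncovered:
        raise ValidationError(
            f"grid classes {sorted(uncovered)} not covered by the transition spec"
        )
    rng = np.random.default_rng(spec.seed)
    out = grid.values.copy()
    code_list = [codes[n] for n in spec.classes]

    if spec.spatial_mode == "iid":
        u = rng.random(grid.values.shape)
        for i, code in enumerate(code_list):
            cum = np.cumsum(spec.rate_matrix[i])
            sel = grid.values == code
            dest_idx = np.searchsorted(cum, u[sel], side="right")
            dest_idx = np.minimum(dest_idx, len(code_list) - 1)
            out[sel] = np.asarray(code_list)[dest_idx]
    else:  # frontier
        boundary = _boundary_mask(grid.values, grid.nodata_code)
        for i, code in enumerate(code_list):
            sel = np.flatnonzero((grid.values == code).ravel())
            if sel.size == 0:
                continue
            stay = spec.rate_matrix[i, i]
            n_move = int(round(sel.size * (1.0 - stay)))
            if n_move == 0:
                continue
            on_edge = boundary.ravel()[sel]
            edge_cells = sel[on_edge]
            interior = sel[~on_edge]
            rng.shuffle(edge_cells)
            rng.shuffle(interior)
            movers = np.concatenate([edge_cells, interior])[:n_move]
            # split movers among destinations j != i proportionally to rates
            dests = [j for j in range(len(code_list)) if j != i]
            w = spec.rate_matrix[i, dests]
            w = w / w.sum()
            counts = np.floor(w * n_move).astype(int)
            # distribute the rounding remainder to the largest rates
            rem = n_move - counts.sum()
            for j in np.argsort(-w)[:rem]:
                counts[j] += 1
            pos = 0
            flat_out = out.ravel()
            for j, c in zip(dests, counts):
                flat_out[movers[pos : pos + c]] = code_list[j]
                pos += c
            out = flat_out.reshape(out.shape)

    return ClassGrid(
        values=out,
        cell_size_m=grid.cell_size_m,
        legend=grid.legend,
        nodata_code=grid.nodata_code,
        epoch_label=grid.epoch_label + "+1" if grid.epoch_label else "evolved",
        origin=grid.origin,
    )


def generate_epoch_series(
    spec: LandscapeSpec,
    transitions: list[TransitionSpec],
    labels: list[str] | None = None,
) -> list[ClassGrid]:
    """Generate an initial landscape and evolve it through each transition."""
    grids = [generate_landscape(spec)]
    for t in transitions:
        grids.append(evolve_landscape(grids[-1], t))
    if labels is not None:
        if len(labels) != len(grids):
            raise ValidationError("need one label per epoch")
        grids = [g.with_label(lab) for g, lab in zip(grids, labels)]
    return grids
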