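"""Categorical raster containers, legends and raster I/O.

A :class:`ClassGrid` is one epoch's ecosystem map: a 2-D integer grid of
class codes plus the cell size and a :class:`Legend` mapping codes to class
names.  Rasters are read and written as ESRI ASCII grids (plain text) or
TIFF (via :mod:`tifffile`, with the georeferencing essentials carried in the
ImageDescription tag).  No reprojection or resampling is performed anywhere:
inputs must already be co-registered, and :func:`check_coregistered` only
verifies that.

Coordinate convention is row-major with the origin at the top-left cell,
matching common raster practice.  Areas are carried internally in m² and
converted to km² / ha only at reporting time.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999

#: the six ecosystem classes used throughout the worked examples
DEFAULT_CLASSES = (
    (1, "forest"),
    (2, "grassland"),
    (3, "wetland"),
    (4, "farmland"),
    (5, "urban"),
    (6, "other-unused"),
)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Legend:
    """Ordered mapping of integer class codes to class names.

    ``analysis_classes`` is the subset of class names singled out for
    reporting (e.g. the five named ecosystem types, with "other-unused"
    participating in totals but hidden from displayed matrices).
    """

    entries: tuple[tuple[int, str], ...]
    analysis_classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise ValidationError(f"legend codes are not unique: {codes}")
        names = {n for _, n in self.entries}
        if self.analysis_classes is not None:
            unknown = set(self.analysis_classes) - names
            if unknown:
                raise ValidationError(
                    f"analysis_classes not in legend: {sorted(unknown)}"
                )

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    def name_of(self, code: int) -> str:
        for c, n in self.entries:
            if c == code:
                return n
        raise KeyError(code)

    def code_of(self, name: str) -> int:
        for c, n in self.entries:
            if n == name:
                return c
        raise KeyError(name)

    def display_names(self) -> tuple[str, ...]:
        """Names reported in tables: ``analysis_classes`` if set, else all."""
        return self.analysis_classes if self.analysis_classes else self.names

    @classmethod
    def default(cls) -> "Legend":
        return cls(
            entries=DEFAULT_CLASSES,
            analysis_classes=("forest", "grassland", "wetland", "farmland", "urban"),
        )

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[int, str],
        analysis_classes: Iterable[str] | None = None,
    ) -> "Legend":
        return cls(
            entries=tuple((int(c), str(n)) for c, n in mapping.items()),
            analysis_classes=tuple(analysis_classes) if analysis_classes else None,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "Legend":
        """Load a legend from YAML (``classes: {code: name}``) or CSV (code,name)."""
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
            if isinstance(doc, dict) and "classes" in doc:
                mapping = doc["classes"]
                analysis = doc.get("analysis_classes")
            else:
                mapping, analysis = doc, None
            return cls.from_mapping(
                {int(k): str(v) for k, v in mapping.items()}, analysis
            )
        entries: list[tuple[int, str]] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in {"code", ""}:
                    continue
                entries.append((int(row[0]), row[1].strip()))
        return cls(entries=tuple(entries))

    def to_yaml(self, path: str | Path) -> None:
        doc: dict = {"classes": {int(c): n for c, n in self.entries}}
        if self.analysis_classes:
            doc["analysis_classes"] = list(self.analysis_classes)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ClassGrid:
    """A 2-D categorical raster for one epoch.

    Invariants enforced at construction: the grid is a non-empty 2-D integer
    array, the cell size is positive, and every non-nodata code appears in
    the legend.
    """

    values: np.ndarray
    cell_size_m: float
    legend: Legend
    nodata_code: int = DEFAULT_NODATA
    epoch_label: str = ""
    origin: tuple[float, float] | None = None  # (xllcorner, yllcorner), if known

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("grid must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError(f"grid dtype must be integer, got {self.values.dtype}")
        if not self.cell_size_m > 0:
            raise ValidationError(f"cell_size_m must be > 0, got {self.cell_size_m}")
        present = set(np.unique(self.values).tolist()) - {self.nodata_code}
        unknown = present - set(self.legend.codes)
        if unknown:
            raise ValidationError(
                f"grid contains codes absent from the legend: {sorted(unknown)}"
            )
        if not present:
            raise ValidationError("grid is entirely nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def cell_area_m2(self) -> float:
        return float(self.cell_size_m) ** 2

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_code

    def total_area_m2(self) -> float:
        """Total non-nodata landscape area in m²."""
        return float(self.valid_mask.sum()) * self.cell_area_m2

    def class_area_m2(self, code: int) -> float:
        return float((self.values == code).sum()) * self.cell_area_m2

    def with_label(self, label: str) -> "ClassGrid":
        return replace(self, epoch_label=label)


def check_coregistered(a: ClassGrid, b: ClassGrid, tol_m: float = 1e-6) -> bool:
    """True iff the two grids share shape, cell size and (if known) origin.

    Mismatches are logged rather than raised; callers that require
    co-registration raise :class:`ValidationError` on a False result.
    """
    if a.shape != b.shape:
        logger.warning("grids not co-registered: shapes %s vs %s", a.shape, b.shape)
        return False
    if abs(a.cell_size_m - b.cell_size_m) > tol_m:
        logger.warning(
            "grids not co-registered: cell sizes %s vs %s", a.cell_size_m, b.cell_size_m
        )
        return False
    if a.origin is not None and b.origin is not None:
        if any(abs(x - y) > tol_m for x, y in zip(a.origin, b.origin)):
            logger.warning(
                "grids not co-registered: origins %s vs %s", a.origin, b.origin
            )
            return False
    return True


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text header + rows, top row first)

def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, int, tuple[float, float] | None]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header or "cellsize" not in header:
        raise ValidationError(f"{path}: not an ESRI ASCII grid (missing header)")
    body = " ".join(lines[i:])
    flat = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if flat.size != nrows * ncols:
        raise ValidationError(
            f"{path}: expected {nrows * ncols} cells, found {flat.size}"
        )
    if not np.all(flat == np.floor(flat)):
        raise ValidationError(f"{path}: grid contains non-integer values")
    values = flat.astype(np.int64).reshape(nrows, ncols)
    nodata = int(header.get("nodata_value", DEFAULT_NODATA))
    origin = None
    if "xllcorner" in header and "yllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"])
    return values, float(header["cellsize"]), nodata, origin


def _write_ascii_grid(grid: ClassGrid, path: Path) -> None:
    ox, oy = grid.origin if grid.origin is not None else (0.0, 0.0)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {ox}\n")
        fh.write(f"yllcorner {oy}\n")
        fh.write(f"cellsize {grid.cell_size_m}\n")
        fh.write(f"NODATA_value {grid.nodata_code}\n")
        for row in grid.values:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# TIFF I/O via tifffile; cell size / origin / nodata ride in ImageDescription

def _read_tiff_grid(path: Path) -> tuple[np.ndarray, float, int, tuple[float, float] | None]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta: dict = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if not np.issubdtype(values.dtype, np.integer):
        if np.all(values == np.floor(values)):
            values = values.astype(np.int64)
        else:
            raise ValidationError(f"{path}: TIFF band is not integer")
    cell = float(meta.get("cell_size_m", 0.0))
    if cell <= 0:
        raise ValidationError(
            f"{path}: TIFF lacks cell_size_m metadata; pass cell_size_m explicitly"
        )
    nodata = int(meta.get("nodata_code", DEFAULT_NODATA))
    origin = tuple(meta["origin"]) if meta.get("origin") else None
    return values.astype(np.int64), cell, nodata, origin


def _write_tiff_grid(grid: ClassGrid, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size_m": grid.cell_size_m,
        "nodata_code": grid.nodata_code,
        "origin": list(grid.origin) if grid.origin is not None else None,
        "epoch_label": grid.epoch_label,
    }
    tifffile.imwrite(path, grid.values.astype(np.int32), description=json.dumps(meta))


def read_class_grid(
    path: str | Path,
    legend: Legend,
    strict: bool = True,
    epoch_label: str = "",
    cell_size_m: float | None = None,
) -> ClassGrid:
    """Read a categorical raster (ESRI ASCII ``.asc``/``.txt`` or TIFF).

    With ``strict`` (the default) any code absent from the legend is an
    error; otherwise unknown codes are mapped to nodata with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values, cell, nodata, origin = _read_tiff_grid(path)
    else:
        values, cell, nodata, origin = _read_ascii_grid(path)
    if cell_size_m is not None:
        cell = float(cell_size_m)
    unknown = set(np.unique(values).tolist()) - set(legend.codes) - {nodata}
    if unknown:
        if strict:
            raise ValidationError(
                f"{path}: codes {sorted(unknown)} not in legend (strict mode)"
            )
        n = int(np.isin(values, sorted(unknown)).sum())
        logger.warning("%s: mapped %d cells with unknown codes to nodata", path, n)
        values = np.where(np.isin(values, sorted(unknown)), nodata, values)
    return ClassGrid(
        values=values,
        cell_size_m=cell,
        legend=legend,
        nodata_code=nodata,
        epoch_label=epoch_label or path.stem,
        origin=origin,
    )


def write_class_grid(grid: ClassGrid, path: str | Path) -> None:
    """Write a grid as ESRI ASCII (``.asc``/``.txt``) or TIFF (``.tif``)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_tiff_grid(grid, path)
    else:
        _write_ascii_grid(grid, path)
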