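"""Three-layer pipeline orchestration.

Layer 1 — basic change: per-epoch class metrics and epoch-pair transfer
matrices.  Layer 2 — why it changed: grey relational degrees between total
landscape area and the composition/pattern indicators, plus the
coupling–coordination / relative-priority diagnosis between the ecosystem
subsystem (class areas) and the landscape-pattern subsystem (NP, PD, LPI,
MPS of a focal class).  Layer 3 — how good the outcome is: entropy-weight
TOPSIS ranking of an objects × indicators change panel.

Everything is driven by a :class:`PipelineConfig` (loadable from YAML); all
outputs are CSV files that re-parse under this package's own readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .coupling import couple_subsystems
from .grey import grey_relational
from .grids import ClassGrid, Legend, ValidationError, read_class_grid
from .metrics import compute_class_metrics
from .topsis import run_topsis
from .transfer import compute_transfer, transfer_to_table
from .weighting import IndicatorPanel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_layer1", "run_layer2", "run_layer3", "run_all"]

LANDSCAPE_INDICATORS = ["NP", "PD", "LPI", "MPS"]


@dataclass
class PipelineConfig:
    epochs: list[tuple[str, str]]  # (label, raster path)
    legend_path: str | None = None
    connectivity: int = 8
    pd_unit: str = "per_100ha"
    rho: float = 0.5
    dimensionless_mode: str = "mean"
    model_form: str = "sqrt"
    beta: tuple[float, float] = (0.5, 0.5)
    priority_thresholds: tuple[float, float] = (1.0, 100.0)
    focal_class: str | None = None  # default: largest class at first epoch
    topsis_panel_path: str | None = None
    display_classes: list[str] | None = None
    out_dir: str = "."
    seed: int = 0
    strict_legend: bool = True
    norm_floor: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        epochs = [(str(e["label"]), str(e["path"])) for e in doc["epochs"]]
        kwargs = {}
        for key in (
            "connectivity", "pd_unit", "rho", "dimensionless_mode", "model_form",
            "focal_class", "display_classes", "out_dir", "seed", "strict_legend",
            "norm_floor",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        if "legend" in doc:
            kwargs["legend_path"] = doc["legend"]
        if "topsis_panel" in doc:
            kwargs["topsis_panel_path"] = doc["topsis_panel"]
        if "beta" in doc:
            kwargs["beta"] = tuple(doc["beta"])
        if "priority_thresholds" in doc:
            kwargs["priority_thresholds"] = tuple(doc["priority_thresholds"])
        return cls(epochs=epochs, **kwargs)

    def legend(self) -> Legend:
        if self.legend_path:
            return Legend.from_file(self.legend_path)
        return Legend.default()

    def load_grids(self) -> list[ClassGrid]:
        if len(self.epochs) < 2:
            raise ValidationError("need at least 2 epochs")
        legend = self.legend()
        return [
            read_class_grid(path, legend, strict=self.strict_legend, epoch_label=label)
            for label, path in self.epochs
        ]


def _epoch_pairs(n: int) -> list[tuple[int, int]]:
    """Consecutive pairs plus the first↔last pair (if not already included)."""
    pairs = [(i, i + 1) for i in range(n - 1)]
    if n > 2:
        pairs.append((0, n - 1))
    return pairs


def run_layer1(
    config: PipelineConfig, grids: list[ClassGrid] | None = None
) -> dict[str, pd.DataFrame]:
    """Metrics table per epoch and transfer table per epoch pair; writes CSVs."""
    grids = grids if grids is not None else config.load_grids()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}
    for g in grids:
        m = compute_class_metrics(
            g, connectivity=config.connectivity, pd_unit=config.pd_unit
        )
        name = f"metrics_{g.epoch_label}"
        m.to_csv(out_dir / f"{name}.csv")
        outputs[name] = m
    for i, j in _epoch_pairs(len(grids)):
        T = compute_transfer(grids[i], grids[j])
        table = transfer_to_table(T, display_classes=config.display_classes)
        name = f"transfer_{grids[i].epoch_label}_{grids[j].epoch_label}"
        table.to_csv(out_dir / f"{name}.csv")
        outputs[name] = table
    return outputs


def build_indicator_panel(
    metrics_by_epoch: dict[str, pd.DataFrame], focal_class: str | None = None
) -> pd.DataFrame:
    """Epochs × indicators panel from layer-1 metrics.

    Columns: total landscape area, each class's area (CA), and the focal
    class's NP/PD/LPI/MPS.  The focal class defaults to the class with the
    largest area at the first epoch.
    """
    epochs = list(metrics_by_epoch)
    first = metrics_by_epoch[epochs[0]]
    if focal_class is None:
        focal_class = first["CA"].idxmax()
    if focal_class not in first.index:
        raise ValidationError(f"focal class {focal_class!r} not in metrics")
    rows = {}
    for label, m in metrics_by_epoch.items():
        row = {"total_area": m.attrs.get("total_landscape_area_ha", m["CA"].sum())}
        for cls in m.index:
            row[f"area_{cls}"] = m.loc[cls, "CA"]
        for ind in LANDSCAPE_INDICATORS:
            row[ind] = m.loc[focal_class, ind]
        rows[label] = row
    panel = pd.DataFrame.from_dict(rows, orient="index")
    # classes absent at every epoch carry no signal and break dimensionless
    # scaling; drop them from the panel
    empty = [c for c in panel.columns
             if c.startswith("area_") and (panel[c] == 0).all()]
    if empty:
        logger.info("dropping classes absent at every epoch: %s", empty)
        panel = panel.drop(columns=empty)
    panel.index.name = "epoch"
    panel.attrs["focal_class"] = focal_class
    return panel


def run_layer2(
    config: PipelineConfig,
    panel: pd.DataFrame | None = None,
    grids: list[ClassGrid] | None = None,
) -> dict[str, pd.DataFrame]:
    """Grey relational table and coupling–coordination table; writes CSVs.

    ``panel`` (epochs × indicators, as from :func:`build_indicator_panel`)
    overrides the automatic construction from layer-1 metrics.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        grids = grids if grids is not None else config.load_grids()
        metrics = {
            g.epoch_label: compute_class_metrics(
                g, connectivity=config.connectivity, pd_unit=config.pd_unit
            )
            for g in grids
        }
        panel = build_indicator_panel(metrics, config.focal_class)
    if len(panel) < 2:
        raise ValidationError("layer 2 needs at least 2 epochs")
    if panel["MPS"].isna().any():
        logger.warning("dropping epochs with undefined MPS (focal class absent)")
        panel = panel.dropna()

    # grey relational: reference = total landscape area
    grey = grey_relational(
        panel, reference="total_area",
        rho=config.rho, mode=config.dimensionless_mode,
    )
    grey_table = pd.DataFrame(
        {"Correlation": grey.degrees.round(3), "Ranking": grey.ranking,
         "Grade": grey.grades}
    ).T
    grey_table.to_csv(out_dir / "grey_correlation.csv")

    # coupling: eco subsystem = class areas, landscape subsystem = NP/PD/LPI/MPS
    area_cols = [c for c in panel.columns if c.startswith("area_")]
    eco = IndicatorPanel(panel[area_cols])
    land = IndicatorPanel(panel[LANDSCAPE_INDICATORS])
    coupling = couple_subsystems(
        eco, land,
        beta=config.beta, model_form=config.model_form,
        priority_thresholds=config.priority_thresholds, floor=config.norm_floor,
    )
    report = pd.DataFrame(
        {
            "Time": coupling.index,
            "C Value": coupling["C"].round(3).values,
            "T Value": coupling["T"].round(3).values,
            "D Value": coupling["D"].round(3).values,
            "Coordination Level": coupling["level"].values,
            "Coupling Coordination Degree": coupling["label"].values,
            "Relative Priority": coupling["priority"].round(3).values,
            "Priority Status": coupling["status"].values,
        }
    ).set_index("Time")
    report.to_csv(out_dir / "coupling_coordination.csv")
    return {"grey": grey_table, "coupling": report, "panel": panel}


def run_layer3(
    config: PipelineConfig, panel: IndicatorPanel | None = None
) -> pd.DataFrame:
    """TOPSIS ranking table; writes CSV."""
    if panel is None:
        if not config.topsis_panel_path:
            raise ValidationError("layer 3 needs a topsis panel (config or argument)")
        panel = IndicatorPanel.from_csv(config.topsis_panel_path)
    result = run_topsis(panel, floor=config.norm_floor)
    table = result.table().round(3)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "topsis_ranking.csv")
    return table


def run_all(config: PipelineConfig) -> dict[str, object]:
    grids = config.load_grids()
    layer1 = run_layer1(config, grids=grids)
    layer2 = run_layer2(config, grids=grids)
    out: dict[str, object] = {"layer1": layer1, "layer2": layer2}
    if config.topsis_panel_path:
        out["layer3"] = run_layer3(config)
    return out
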