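import math

import numpy as np
import pandas as pd
import pytest

from ecopattern import (
    ValidationError,
    compute_class_metrics,
    label_patches,
    metrics_delta,
)

from conftest import make_grid
from oracles import flood_fill_patches, naive_class_metrics


class TestLabelPatches:
    def test_uniform_grid_is_one_patch(self, uniform_grid):
        assert label_patches(uniform_grid).n_patches == 1

    def test_invalid_connectivity(self, uniform_grid):
        with pytest.raises(ValidationError, match="connectivity"):
            label_patches(uniform_grid, connectivity=6)

    def test_diagonal_contact_contract(self, small_legend):
        """Two same-class cells touching only at a corner are two patches
        under rook connectivity and one under queen."""
        grid = make_grid([[1, 2], [2, 1]], small_legend)
        lab4 = label_patches(grid, connectivity=4)
        lab8 = label_patches(grid, connectivity=8)
        forest4 = [p for p, c in lab4.patch_class.items() if c == 1]
        forest8 = [p for p, c in lab8.patch_class.items() if c == 1]
        assert len(forest4) == 2
        assert len(forest8) == 1

    def test_labels_partition_each_class(self, random_grid):
        lab = label_patches(random_grid)
        for pid, code in lab.patch_class.items():
            cells = random_grid.values[lab.labels == pid]
            assert (cells == code).all()
        assert sum(lab.patch_cells.values()) == int(random_grid.valid_mask.sum())

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_patch_count_matches_flood_fill(self, random_grid, connectivity):
        ours = label_patches(random_grid, connectivity)
        _, oracle_class, _ = flood_fill_patches(
            random_grid.values, random_grid.nodata_code, connectivity
        )
        assert ours.n_patches == len(oracle_class)


class TestClassMetrics:
    def test_uniform_closed_form(self, uniform_grid):
        """10×10 single-class grid at 100 m: CA = 100 ha, NP = 1,
        PLAND = LPI = 100 %, MPS = 100 ha, PD = 1 per 100 ha."""
        m = compute_class_metrics(uniform_grid)
        row = m.loc["forest"]
        assert row["CA"] == pytest.approx(100.0)
        assert row["NP"] == 1
        assert row["PLAND"] == pytest.approx(100.0)
        assert row["LPI"] == pytest.approx(100.0)
        assert row["MPS"] == pytest.approx(100.0)
        assert row["PD"] == pytest.approx(1.0)

    def test_two_square_patches_closed_form(self, legend):
        """Two disjoint 2×2 squares in a 10×10 grid at 100 m cells:
        CA = 8 ha, NP = 2, MPS = 4 ha, LPI = 4 %."""
        values = np.full((10, 10), legend.code_of("farmland"))
        values[0:2, 0:2] = legend.code_of("forest")
        values[5:7, 5:7] = legend.code_of("forest")
        m = compute_class_metrics(make_grid(values, legend))
        row = m.loc["forest"]
        assert row["CA"] == pytest.approx(8.0)
        assert row["NP"] == 2
        assert row["MPS"] == pytest.approx(4.0)
        assert row["LPI"] == pytest.approx(4.0)

    def test_absent_class_has_nan_mps(self, uniform_grid):
        m = compute_class_metrics(uniform_grid)
        assert m.loc["urban", "NP"] == 0
        assert math.isnan(m.loc["urban", "MPS"])

    def test_pland_sums_to_100(self, random_grid):
        m = compute_class_metrics(random_grid)
        assert m["PLAND"].sum() == pytest.approx(100.0, rel=1e-9)

    def test_mps_times_np_is_ca(self, random_grid):
        m = compute_class_metrics(random_grid)
        present = m[m["NP"] > 0]
        np.testing.assert_allclose(
            present["MPS"] * present["NP"], present["CA"], rtol=1e-9
        )

    def test_lpi_bounded_by_pland(self, random_grid):
        m = compute_class_metrics(random_grid)
        present = m[m["NP"] > 0]
        assert (present["LPI"] > 0).all()
        assert (present["LPI"] <= present["PLAND"] + 1e-12).all()

    def test_ca_conserves_landscape_area(self, random_grid):
        m = compute_class_metrics(random_grid)
        assert m["CA"].sum() == pytest.approx(
            m.attrs["total_landscape_area_ha"], rel=1e-12
        )

    def test_nodata_excluded_from_denominators(self, legend):
        values = np.ones((10, 10), dtype=np.int64)
        values[0, :] = -9999
        m = compute_class_metrics(make_grid(values, legend))
        assert m.attrs["total_landscape_area_ha"] == pytest.approx(90.0)
        assert m.loc["forest", "PLAND"] == pytest.approx(100.0)

    def test_pd_unit_options(self, uniform_grid):
        per_ha = compute_class_metrics(uniform_grid, pd_unit="per_ha")
        per_km2 = compute_class_metrics(uniform_grid, pd_unit="per_km2")
        assert per_ha.loc["forest", "PD"] == pytest.approx(0.01)
        assert per_km2.loc["forest", "PD"] == pytest.approx(1.0)

    def test_bridging_cell_monotonicity(self, legend):
        """Connecting two patches of a class never decreases LPI."""
        values = np.full((10, 10), legend.code_of("farmland"))
        values[4, 0:4] = legend.code_of("forest")
        values[4, 6:10] = legend.code_of("forest")
        before = compute_class_metrics(make_grid(values, legend))
        bridged = values.copy()
        bridged[4, 4:6] = legend.code_of("forest")
        after = compute_class_metrics(make_grid(bridged, legend))
        assert after.loc["forest", "LPI"] >= before.loc["forest", "LPI"]
        assert after.loc["forest", "NP"] < before.loc["forest", "NP"]


@pytest.mark.parametrize("connectivity", [4, 8])
def test_metrics_match_naive_oracle_on_random_grids(small_legend, connectivity):
    """All six metrics agree exactly with a cell-by-cell flood-fill
    recomputation on 50 seeded random grids up to 30×30."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        shape = tuple(rng.integers(5, 31, size=2))
        values = rng.choice([1, 2, 3, -9999], p=[0.35, 0.3, 0.3, 0.05], size=shape)
        if not (values != -9999).any():
            values[0, 0] = 1
        grid = make_grid(values, small_legend, cell_size_m=30.0)
        ours = compute_class_metrics(grid, connectivity=connectivity)
        oracle = naive_class_metrics(
            grid.values, grid.nodata_code, grid.cell_size_m,
            small_legend.codes, connectivity,
        )
        for code in small_legend.codes:
            name = small_legend.name_of(code)
            for metric, expected in oracle[code].items():
                got = ours.loc[name, metric]
                if isinstance(expected, float) and math.isnan(expected):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, rel=1e-12), (
                        f"{name} {metric}"
                    )


class TestMetricsDelta:
    def test_identical_tables_give_zero(self, random_grid):
        m = compute_class_metrics(random_grid)
        d = metrics_delta(m, m)
        present = m["NP"] > 0
        assert (d[present].fillna(0.0) == 0).all().all()

    def test_signed_difference(self, legend):
        a = np.ones((10, 10), dtype=np.int64)
        b = a.copy()
        b[0, 0] = legend.code_of("urban")  # forest CA 100 → 99 ha
        da = compute_class_metrics(make_grid(a, legend))
        db = compute_class_metrics(make_grid(b, legend))
        d = metrics_delta(da, db)
        assert d.loc["forest", "CA"] == pytest.approx(-1.0)

    def test_removed_patch_delta(self, legend):
        """Deleting one of two patches changes NP by −1 and LPI accordingly."""
        before = np.full((10, 10), legend.code_of("farmland"))
        before[0:2, 0:2] = legend.code_of("forest")
        before[5:8, 5:8] = legend.code_of("forest")  # larger patch, 9 cells
        after = before.copy()
        after[0:2, 0:2] = legend.code_of("farmland")
        d = metrics_delta(
            compute_class_metrics(make_grid(before, legend)),
            compute_class_metrics(make_grid(after, legend)),
        )
        assert d.loc["forest", "NP"] == -1
        assert d.loc["forest", "LPI"] == pytest.approx(0.0)  # largest patch kept
        assert d.loc["forest", "CA"] == pytest.approx(-4.0)

    def test_class_set_mismatch_rejected(self, random_grid, uniform_grid):
        a = compute_class_metrics(random_grid)
        b = compute_class_metrics(uniform_grid)
        with pytest.raises(ValidationError, match="class sets"):
            metrics_delta(a, b)
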