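import math

import numpy as np
import pandas as pd
import pytest

from ecopattern import (
    IndicatorPanel,
    ValidationError,
    combine_coupling,
    composite_value,
    coordination_degree,
    couple_subsystems,
    coupling_degree,
    grade_coordination,
    relative_priority,
)

# the published level-9 zone table: (C, T) → D and grade
PUBLISHED_ROWS = [
    ("2000", 0.846, 0.602, 0.714, 8, "Moderate coordination"),
    ("2005", 0.02, 0.5, 0.1, 2, "Serious imbalance"),
    ("2010", 0.369, 0.346, 0.358, 4, "Mild imbalance"),
    ("2015", 0.02, 0.5, 0.1, 2, "Serious imbalance"),
    ("2018", 0.22, 0.35, 0.277, 3, "Moderate imbalance"),
]


class TestComposite:
    def test_all_ones_gives_one(self):
        norm = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        w = pd.Series({"a": 0.3, "b": 0.7})
        np.testing.assert_allclose(composite_value(norm, w), 1.0)

    def test_equal_weights_average(self):
        norm = pd.DataFrame({"a": [0.2], "b": [0.8]}, index=["e"])
        w = pd.Series({"a": 0.5, "b": 0.5})
        # bypass the 2-row panel rule: composite works on any normalized frame
        norm2 = pd.concat([norm, norm])
        assert composite_value(norm2, w).iloc[0] == pytest.approx(0.5)

    def test_degenerate_weight_selects_indicator(self):
        norm = pd.DataFrame({"a": [0.3, 0.3], "b": [0.7, 0.1]})
        w = pd.Series({"a": 0.0, "b": 1.0})
        np.testing.assert_allclose(composite_value(norm, w), [0.7, 0.1])

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="match"):
            composite_value(pd.DataFrame({"a": [0.1, 0.2]}), pd.Series({"b": 1.0}))


class TestCouplingDegree:
    def test_equal_values_give_one(self):
        assert coupling_degree([0.5, 0.5]) == pytest.approx(1.0)

    def test_vanishing_subsystem_gives_zero(self):
        assert coupling_degree([0.5, 0.0]) == 0.0

    def test_closed_form(self):
        """(0.8, 0.2): 2·√0.16 / 1.0 = 0.8."""
        assert coupling_degree([0.8, 0.2]) == pytest.approx(0.8)

    def test_all_zero_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            assert coupling_degree([0.0, 0.0]) == 0.0

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            u1, u2 = rng.random(2) + 0.01
            k = rng.random() * 5 + 0.1
            assert coupling_degree([u1, u2]) == pytest.approx(
                coupling_degree([u2, u1]), rel=1e-12
            )
            assert coupling_degree([k * u1, k * u2]) == pytest.approx(
                coupling_degree([u1, u2]), rel=1e-9
            )

    def test_bounded_by_one(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            u = rng.random(rng.integers(2, 5)) + 1e-6
            assert 0.0 <= coupling_degree(u) <= 1.0

    def test_three_subsystems(self):
        assert coupling_degree([0.4, 0.4, 0.4]) == pytest.approx(1.0)


class TestCoordination:
    def test_t_is_weighted_mean(self):
        T, D = coordination_degree(0.5, [0.2, 0.8], beta=[0.25, 0.75])
        assert T == pytest.approx(0.65)
        assert D == pytest.approx(math.sqrt(0.5 * 0.65))

    def test_default_beta_even(self):
        T, _ = coordination_degree(1.0, [0.3, 0.7])
        assert T == pytest.approx(0.5)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValidationError, match="beta"):
            coordination_degree(0.5, [0.5, 0.5], beta=[0.9, 0.9])

    def test_perfect_state_both_forms(self):
        assert combine_coupling(1.0, 1.0, "sqrt") == pytest.approx(1.0)
        assert combine_coupling(1.0, 1.0, "literal") == pytest.approx(1.0)

    def test_unknown_model_form(self):
        with pytest.raises(ValidationError, match="model_form"):
            combine_coupling(0.5, 0.5, "geometric")

    @pytest.mark.parametrize("label,C,T,D,level,name", PUBLISHED_ROWS)
    def test_published_rows_under_sqrt_form(self, label, C, T, D, level, name):
        """All five published (C, T) pairs reproduce the printed D within
        ±0.001 under the square-root model form, with the printed grade."""
        d = combine_coupling(C, T, "sqrt")
        assert d == pytest.approx(D, abs=1e-3)
        got_level, got_name = grade_coordination(d)
        assert (got_level, got_name) == (level, name)

    def test_literal_form_fails_published_2000_row(self):
        """D = C·T misses the printed 2000 value by more than 0.1 — the
        regression pinning why "sqrt" is the default model form."""
        d = combine_coupling(0.846, 0.602, "literal")
        assert abs(d - 0.714) > 0.1

    def test_monotone_in_c_and_t(self):
        base = combine_coupling(0.5, 0.5)
        assert combine_coupling(0.6, 0.5) > base
        assert combine_coupling(0.5, 0.6) > base


class TestGrading:
    @pytest.mark.parametrize(
        "D,level",
        [(0.05, 1), (0.1, 2), (0.15, 2), (0.277, 3), (0.358, 4), (0.5, 6),
         (0.714, 8), (0.9, 10), (1.0, 10)],
    )
    def test_bins_lower_inclusive(self, D, level):
        got_level, label = grade_coordination(D)
        assert got_level == level

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            grade_coordination(1.5)


class TestPriority:
    def test_equal_composites_synchronous(self):
        P, status = relative_priority(0.5, 0.5)
        assert P == pytest.approx(1.0)
        assert status == "synchronous"

    def test_lag(self):
        P, status = relative_priority(0.3, 0.6)
        assert P == pytest.approx(0.5)
        assert status == "lag"

    def test_ratio_two_is_synchronous(self):
        P, status = relative_priority(0.6, 0.3)
        assert P == pytest.approx(2.0)
        assert status == "synchronous"

    def test_lead_beyond_upper_threshold(self):
        _, status = relative_priority(0.5, 0.001)
        assert status == "lead"

    def test_custom_thresholds(self):
        _, status = relative_priority(0.6, 0.3, thresholds=(1.0, 1.5))
        assert status == "lead"

    def test_zero_landscape_rejected(self):
        with pytest.raises(ValidationError):
            relative_priority(0.5, 0.0)


class TestCoupleSubsystems:
    def make_panels(self, seed=3, n=5):
        rng = np.random.default_rng(seed)
        idx = [str(2000 + 5 * i) for i in range(n)]
        eco = IndicatorPanel(
            pd.DataFrame(rng.random((n, 3)) * 100, index=idx,
                         columns=["area_forest", "area_grassland", "area_farmland"])
        )
        land = IndicatorPanel(
            pd.DataFrame(rng.random((n, 4)) * 10, index=idx,
                         columns=["NP", "PD", "LPI", "MPS"])
        )
        return eco, land

    def test_step_by_step_oracle(self):
        """The table equals an explicit normalize → weight → composite → C
        → T → D chain computed by hand here."""
        from ecopattern import entropy_weights, range_normalize

        eco, land = self.make_panels(seed=8)
        table = couple_subsystems(eco, land)
        eco_norm = range_normalize(eco)
        land_norm = range_normalize(land)
        u_eco = composite_value(eco_norm, entropy_weights(eco_norm))
        u_land = composite_value(land_norm, entropy_weights(land_norm))
        for epoch in eco.data.index:
            C = coupling_degree([u_eco[epoch], u_land[epoch]])
            T = 0.5 * (u_eco[epoch] + u_land[epoch])
            D = math.sqrt(C * T)
            assert table.loc[epoch, "C"] == pytest.approx(C, rel=1e-12)
            assert table.loc[epoch, "T"] == pytest.approx(T, rel=1e-12)
            assert table.loc[epoch, "D"] == pytest.approx(D, rel=1e-12)

    def test_d_squared_equals_c_times_t(self):
        eco, land = self.make_panels(seed=5)
        table = couple_subsystems(eco, land)
        np.testing.assert_allclose(table["D"] ** 2, table["C"] * table["T"],
                                   atol=1e-9)

    def test_lag_status_when_eco_below_land(self):
        idx = ["2000", "2005", "2010"]
        eco = IndicatorPanel(
            pd.DataFrame({"area_forest": [1.0, 2.0, 3.0],
                          "area_farmland": [1.0, 2.0, 3.0]}, index=idx)
        )
        # landscape indicators vary oppositely so its composite is higher
        land = IndicatorPanel(
            pd.DataFrame({"NP": [3.0, 2.0, 1.0], "PD": [3.0, 2.0, 1.0],
                          "LPI": [6.0, 4.0, 2.0], "MPS": [9.0, 5.0, 1.0]}, index=idx)
        )
        table = couple_subsystems(eco, land)
        lagged = table[table["U_eco"] < table["U_land"]]
        assert (lagged["status"] == "lag").all()

    def test_mismatched_epochs_rejected(self):
        eco, land = self.make_panels()
        land.data.index = ["x"] * len(land.data)
        with pytest.raises(ValidationError, match="epoch"):
            couple_subsystems(eco, land)
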