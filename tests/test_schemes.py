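import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beegs.schemes import (
    BaseProgram,
    EmptyFeasibleSetError,
    InvalidFractionError,
    MissingGridPointError,
    OutOfRangeError,
    SchemeGrid,
    derive_scheme,
    enumerate_and_optimize,
    interpolate_accuracy,
    predict_gain,
    selection_intensity,
)


class TestSelectionIntensity:
    @pytest.mark.parametrize(
        "sel,cand,expected,dp",
        [
            (50, 1000, 2.06, 2),
            (200, 1000, 1.40, 2),
            (8, 64, 1.65, 2),
            (8, 9, 0.21, 2),
            (5, 32, 1.53, 2),
            (5, 6, 0.30, 2),
            (8, 22, 1.0324, 4),
            (5, 7, 0.4759, 4),
        ],
    )
    def test_published_values(self, sel, cand, expected, dp):
        assert round(float(selection_intensity(sel, cand)), dp) == expected

    def test_select_everyone_is_zero(self):
        assert selection_intensity(7, 7) == 0.0

    def test_half_selected_closed_form(self):
        # phi(0) / 0.5 = 2 / sqrt(2 pi)
        assert selection_intensity(1, 2) == pytest.approx(0.7979, abs=5e-5)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidFractionError):
            selection_intensity(0, 10)
        with pytest.raises(InvalidFractionError):
            selection_intensity(11, 10)

    @settings(max_examples=40, deadline=None)
    @given(p=st.floats(0.005, 0.995))
    def test_monotone_in_selected_proportion(self, p):
        n = 10_000
        k = max(1, int(p * n))
        if k + 50 <= n:
            assert selection_intensity(k, n) >= selection_intensity(k + 50, n)


class TestDeriveScheme:
    def test_reference_preselection_example(self):
        s = derive_scheme(1000, 30, 16, 50, 10)
        assert s.p_DPQ == pytest.approx(0.6)
        assert s.N_rest == 20
        assert s.p_ref == pytest.approx(0.27)
        assert s.feasible

    def test_no_preselection_fills_reference(self):
        s = derive_scheme(1000, 0, 9, 0, 6)
        assert s.p_DPQ == 0 and s.p_BQ == 0
        assert s.p_ref == 1.0
        assert s.i_DPQ_GPS == 0.0 and s.i_BQ_GPS == 0.0

    def test_over_budget_is_infeasible(self):
        s = derive_scheme(500, 0, 9, 200, 32)
        assert not s.feasible
        with pytest.raises(EmptyFeasibleSetError):
            predict_gain(s, 0.5, 0.5, 1.0, 1.0)

    def test_cbs_intensities_fixed_by_base_program(self):
        s = derive_scheme(0, 0, 9, 0, 6)
        assert round(s.i_DPQ_CBS, 2) == 2.06
        assert round(s.i_BQ_CBS, 2) == 1.40

    def test_out_of_range_rejected(self):
        with pytest.raises(OutOfRangeError):
            derive_scheme(1000, 51, 16, 50, 10)
        with pytest.raises(OutOfRangeError):
            derive_scheme(1000, 30, 8, 50, 10)


@pytest.fixture
def accuracy_table():
    return pd.DataFrame(
        {
            "analysis": ["PBLUP"]
            + ["ssGBLUP_BQ"] * 6
            + ["ssGBLUP_DPQ+BQ"] * 6,
            "p_ref": [0.0] + [0.05, 0.1, 0.2, 0.3, 0.5, 1.0] * 2,
            "rho_pW": [0.55, 0.56, 0.57, 0.58, 0.59, 0.60, 0.62,
                       0.57, 0.58, 0.59, 0.60, 0.61, 0.62],
            "rho_uQ": [0.18, 0.20, 0.24, 0.30, 0.34, 0.40, 0.47,
                       0.28, 0.31, 0.35, 0.38, 0.42, 0.48],
        }
    )


class TestInterpolation:
    def test_grid_point_returns_tabulated_value(self, accuracy_table):
        pw, uq = interpolate_accuracy(0.3, accuracy_table, "ssGBLUP_BQ")
        assert uq == pytest.approx(0.34)

    def test_zero_returns_pblup(self, accuracy_table):
        pw, uq = interpolate_accuracy(0.0, accuracy_table, "ssGBLUP_BQ")
        assert pw == pytest.approx(0.55) and uq == pytest.approx(0.18)

    def test_linear_midpoint(self, accuracy_table):
        pw, uq = interpolate_accuracy(0.15, accuracy_table, "ssGBLUP_BQ")
        assert uq == pytest.approx((0.24 + 0.30) / 2)

    def test_missing_analysis_rejected(self, accuracy_table):
        with pytest.raises(MissingGridPointError):
            interpolate_accuracy(0.3, accuracy_table.iloc[:1], "ssGBLUP_BQ")


class TestPredictGain:
    def test_pure_cbs_hand_value(self):
        s = derive_scheme(0, 0, 9, 0, 6)
        g = predict_gain(s, rho_pW=0.5, rho_uQ=0.0, sigma_pW=1.0, sigma_uQ=1.0)
        expected = 0.5 * (s.i_DPQ_CBS + s.i_BQ_CBS) * 0.5
        assert g.R_GS == pytest.approx(expected)
        assert g.R_GPS == 0.0

    def test_gps_term_vanishes_without_preselection(self):
        s = derive_scheme(2000, 0, 9, 0, 6)
        g = predict_gain(s, 0.6, 0.5, 1.0, 1.4)
        assert g.R_GPS == 0.0
        assert g.R_GS == g.R_CBS

    def test_term_by_term_hand_evaluation(self):
        s = derive_scheme(2000, 40, 20, 100, 12)
        g = predict_gain(s, 0.61, 0.42, 0.87, 1.21)
        r_cbs = 0.5 * (s.i_DPQ_CBS + s.i_BQ_CBS) * 0.61 * 0.87
        r_gps = (
            0.5 * s.i_DPQ_GPS * s.p_DPQ * 0.42 * 1.21
            + 0.5 * s.i_BQ_GPS * s.p_BQ * 0.42 * 1.21
        )
        assert g.R_CBS == pytest.approx(r_cbs, abs=1e-12)
        assert g.R_GPS == pytest.approx(r_gps, abs=1e-12)
        assert g.R_GS == pytest.approx(r_cbs + r_gps, abs=1e-12)

    def test_monotone_in_inputs(self):
        s = derive_scheme(2000, 40, 20, 100, 12)
        base = predict_gain(s, 0.5, 0.4, 1.0, 1.2).R_GS
        assert predict_gain(s, 0.6, 0.4, 1.0, 1.2).R_GS >= base
        assert predict_gain(s, 0.5, 0.5, 1.0, 1.2).R_GS >= base
        assert predict_gain(s, 0.5, 0.4, 1.1, 1.2).R_GS >= base
        assert predict_gain(s, 0.5, 0.4, 1.0, 1.3).R_GS >= base


SMALL_GRID = SchemeGrid(
    budgets=(0, 500, 1000, 1500),
    N_DPQ_GPS=(0, 50),
    N_BQ_GPS=(0, 200),
    n_DPQ_GPS=(9, 24),
    n_BQ_GPS=(6, 16),
)


class TestEnumeration:
    def test_budget_zero_optimum_is_pure_pedigree(self, accuracy_table):
        res = enumerate_and_optimize(
            accuracy_table, sigma_pW=0.8, sigma_uQ=1.4, grid=SMALL_GRID
        )
        first = res.iloc[0]
        assert first.analysis == "PBLUP"
        assert first.R_GPS == pytest.approx(0.0)
        s = derive_scheme(0, 0, 9, 0, 6)
        r_pb = predict_gain(s, 0.55, 0.18, 0.8, 1.4).R_GS
        assert first.R_GS == pytest.approx(r_pb)

    def test_gain_non_decreasing_in_budget(self, accuracy_table):
        res = enumerate_and_optimize(
            accuracy_table, sigma_pW=0.8, sigma_uQ=1.4, grid=SMALL_GRID
        )
        assert res.R_GS.is_monotonic_increasing
        assert (res.IGG.dropna() >= -1e-12).all()

    def test_degenerate_table_makes_gps_worthless(self):
        # if genomic accuracies equal PBLUP's, preselection with zero
        # uQ-accuracy gain cannot beat spending everything on reference
        table = pd.DataFrame(
            {
                "analysis": ["PBLUP", "ssGBLUP_BQ", "ssGBLUP_BQ"],
                "p_ref": [0.0, 0.05, 1.0],
                "rho_pW": [0.55, 0.55, 0.55],
                "rho_uQ": [0.18, 0.18, 0.18],
            }
        )
        res = enumerate_and_optimize(
            table, sigma_pW=0.8, sigma_uQ=1.4, grid=SMALL_GRID,
            use_dpq_accuracy_when_all_preselected=False,
        )
        # optima still include nonneg GPS terms; R_CBS is flat by design
        assert res.R_CBS.nunique() == 1
        # tie-break picks the scheme using fewest genotypes at budget 0
        assert res.iloc[0].N_DPQ_GPS == 0 and res.iloc[0].N_BQ_GPS == 0

    def test_dpq_accuracy_used_when_all_dpq_preselected(self, accuracy_table):
        res = enumerate_and_optimize(
            accuracy_table, sigma_pW=0.8, sigma_uQ=1.4,
            grid=SchemeGrid(budgets=(4000,), n_DPQ_GPS=(9, 64), n_BQ_GPS=(6, 32)),
        )
        row = res.iloc[0]
        if row.p_DPQ == 1.0:
            assert row.analysis == "ssGBLUP_DPQ+BQ"
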