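"""Transport-physics models: conductance, exclusion drop, selectivity,
mobility inference and the PEG diameter bracket."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cntpore.transport_models import (
    ElectrolyteState,
    ExclusionModel,
    PegCalibration,
    PoreGeometry,
    SelectivityMeasurement,
    delta_g_from_blockade,
    estimate_diameter_from_peg,
    exclusion_delta_g,
    infer_mobility_factor,
    kcl_activity,
    kcl_activity_coefficient,
    nernst_potential,
    peg_hydrodynamic_diameter,
    reversal_from_transference,
    selectivity_ratio,
    transference_from_reversal,
    transference_from_selectivity,
    tube_conductance,
)

ELEC_1M = ElectrolyteState(c_kcl_molar=1.0)

positive = st.floats(min_value=0.05, max_value=100.0,
                     allow_nan=False, allow_infinity=False)


class TestTubeConductance:
    def test_hand_computed_reference_tube(self):
        """1.2 nm x 10 nm tube in 1 M KCl with bulk mobilities: 1.69 nS."""
        g = tube_conductance(PoreGeometry(1.2, 10.0), ELEC_1M)
        assert g == pytest.approx(1.69, abs=0.01)

    def test_vanishes_with_diameter(self):
        g = tube_conductance(PoreGeometry(1e-6, 10.0), ELEC_1M)
        assert g < 1e-10

    @settings(max_examples=50, deadline=None)
    @given(d=positive, length=positive)
    def test_geometric_scaling_laws(self, d, length):
        """G scales as D^2 at fixed L and as 1/L at fixed D."""
        g = tube_conductance(PoreGeometry(d, length), ELEC_1M)
        g2d = tube_conductance(PoreGeometry(2 * d, length), ELEC_1M)
        g2l = tube_conductance(PoreGeometry(d, 2 * length), ELEC_1M)
        assert g2d == pytest.approx(4.0 * g, rel=1e-9)
        assert g2l == pytest.approx(0.5 * g, rel=1e-9)

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(ValueError):
            PoreGeometry(0.0, 10.0)
        with pytest.raises(ValueError):
            PoreGeometry(1.2, -1.0)


class TestExclusionDrop:
    def test_hand_computed_reference_drop(self):
        """1.0 nm analyte in a 10 nm pore, 1 M KCl: 1.18 nS drop."""
        dg = exclusion_delta_g(PoreGeometry(1.2, 10.0), ELEC_1M,
                               ExclusionModel(d_analyte_nm=1.0))
        assert dg == pytest.approx(1.18, abs=0.01)

    def test_vanishing_analyte_gives_zero_drop(self):
        dg = exclusion_delta_g(PoreGeometry(1.2, 10.0), ELEC_1M,
                               ExclusionModel(d_analyte_nm=1e-8))
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_complete_block_equals_open_pore_conductance(self):
        """An analyte as wide as the pore removes the full conductance."""
        geom = PoreGeometry(1.2, 10.0)
        dg = exclusion_delta_g(geom, ELEC_1M,
                               ExclusionModel(d_analyte_nm=1.2))
        assert dg == pytest.approx(tube_conductance(geom, ELEC_1M), rel=1e-9)

    def test_counterion_term_can_cancel_exclusion(self):
        geom = PoreGeometry(1.2, 10.0)
        base = exclusion_delta_g(geom, ELEC_1M, ExclusionModel(1.0))
        # choose mu* q* to cancel the exclusion term exactly
        from cntpore.constants import IONS_PER_M3_PER_MOLAR
        q = base * 1e-9 * (geom.length_nm * 1e-9) / IONS_PER_M3_PER_MOLAR
        dg = exclusion_delta_g(geom, ELEC_1M,
                               ExclusionModel(1.0, mu_k_star=1.0,
                                              q_star_c_per_m=q))
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_analyte_larger_than_pore_rejected(self):
        with pytest.raises(ValueError, match="cannot enter"):
            exclusion_delta_g(PoreGeometry(1.2, 10.0), ELEC_1M,
                              ExclusionModel(d_analyte_nm=1.5))


class TestMobilityInference:
    def test_identity(self):
        assert infer_mobility_factor(0.385, 10.0, 0.385, 10.0) == 1.0

    def test_printed_drop_values(self):
        """Nanotube vs alpha-hemolysin drops at equal length: 4.05x."""
        assert infer_mobility_factor(0.385, 10.0, 0.095, 10.0) == pytest.approx(
            4.05, abs=0.01)

    def test_length_interval_propagates(self):
        lo, hi = infer_mobility_factor(0.385, (5.0, 15.0), 0.056, 10.0)
        assert lo == pytest.approx(3.44, abs=0.01)
        assert hi == pytest.approx(10.3, abs=0.05)

    @settings(max_examples=25, deadline=None)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        base = infer_mobility_factor(0.385, 10.0, 0.095, 10.0)
        scaled = infer_mobility_factor(k * 0.385, 10.0, k * 0.095, 10.0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            infer_mobility_factor(0.385, 10.0, 0.0, 10.0)


class TestBlockadeToDrop:
    @pytest.mark.parametrize(
        "frac,i0,v,expected",
        [(0.090, 105.0, 100.0, 0.0945),
         (0.034, 166.0, 100.0, 0.0564),
         (0.442, 70.0, 80.0, 0.3868)],
    )
    def test_fractional_blockade_times_conductance(self, frac, i0, v, expected):
        assert delta_g_from_blockade(frac, i0, v) == pytest.approx(
            expected, abs=2e-4)


class TestSelectivityChain:
    def test_nernst_zero_at_equal_activities(self):
        assert nernst_potential(0.5, 0.5) == 0.0

    def test_nernst_decade_ratio(self):
        """RT/F ln(10) at 298.15 K is the textbook 59.2 mV per decade."""
        assert nernst_potential(1.0, 0.1) == pytest.approx(59.2, abs=0.1)

    def test_nernst_antisymmetry(self):
        assert nernst_potential(0.3, 0.9) == pytest.approx(
            -nernst_potential(0.9, 0.3), rel=1e-12)

    def test_transference_from_reference_reversal(self):
        """The study's activity gradient and -19.2 mV give T_K ~ 0.6815."""
        meas = SelectivityMeasurement(a_cis=kcl_activity(0.1),
                                      a_trans=kcl_activity(1.0),
                                      reversal_potential_mv=-19.2)
        assert transference_from_reversal(meas) == pytest.approx(0.6815,
                                                                 abs=5e-4)

    def test_zero_reversal_is_nonselective(self):
        meas = SelectivityMeasurement(0.077, 0.604, 0.0)
        assert transference_from_reversal(meas) == pytest.approx(0.5)

    def test_reversal_at_nernst_limit_clips_with_warning(self):
        de = nernst_potential(0.077, 0.604)
        meas = SelectivityMeasurement(0.077, 0.604, de * 1.001)
        with pytest.warns(UserWarning, match="outside"):
            t = transference_from_reversal(meas)
        assert 0.0 < t < 1.0

    def test_equal_activities_not_identifiable(self):
        with pytest.raises(ValueError, match="identifiable"):
            transference_from_reversal(SelectivityMeasurement(0.6, 0.6, -5.0))

    def test_selectivity_ratio_basics(self):
        assert selectivity_ratio(0.5) == pytest.approx(1.0)
        assert selectivity_ratio(0.6815) == pytest.approx(2.14, abs=0.01)

    def test_selectivity_boundaries_raise(self):
        for t in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError, match="boundary"):
                selectivity_ratio(t)

    @settings(max_examples=50, deadline=None)
    @given(sr=st.floats(min_value=1e-3, max_value=1e3),
           t_k=st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_roundtrips(self, sr, t_k):
        assert selectivity_ratio(transference_from_selectivity(sr)) == \
            pytest.approx(sr, rel=1e-9)
        assert transference_from_selectivity(selectivity_ratio(t_k)) == \
            pytest.approx(t_k, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(t_k=st.floats(min_value=0.01, max_value=0.99))
    def test_ghk_forward_inverse_identity(self, t_k):
        a_cis, a_trans = kcl_activity(0.1), kcl_activity(1.0)
        v_r = reversal_from_transference(t_k, a_cis, a_trans)
        meas = SelectivityMeasurement(a_cis, a_trans, v_r)
        assert transference_from_reversal(meas) == pytest.approx(t_k, rel=1e-9)


class TestActivities:
    def test_tabulated_coefficients(self):
        assert kcl_activity_coefficient(0.1) == pytest.approx(0.770)
        assert kcl_activity_coefficient(1.0) == pytest.approx(0.604)

    def test_interpolation_monotone_between_table_points(self):
        g = [kcl_activity_coefficient(c) for c in (0.1, 0.3, 0.5)]
        assert g[0] > g[1] > g[2]

    def test_davies_fallback_below_table(self):
        g = kcl_activity_coefficient(1e-4)
        assert 0.98 < g < 1.0


class TestPegDiameter:
    def test_reference_exclusion_table_brackets_pore(self):
        """Strong-to-weak blockade collapse between 1.2 and 1.5 nm PEG."""
        cal = PegCalibration(
            mw_da=(62, 200, 400, 600, 4000),
            dh_nm=(0.6, 0.9, 1.2, 1.5, 2.0),
            blockade_frac=(0.05, 0.06, 0.07, 0.45, 0.46),
        )
        assert estimate_diameter_from_peg(cal) == (1.2, 1.5)

    def test_flat_table_warns_widest_bracket(self):
        cal = PegCalibration((62, 200, 400), (0.6, 0.9, 1.2),
                             (0.2, 0.2, 0.2))
        with pytest.warns(UserWarning, match="no exclusion transition"):
            assert estimate_diameter_from_peg(cal) == (0.6, 1.2)

    def test_jump_at_first_pair(self):
        """Brute-force max step: largest adjacent difference wins."""
        blockades = (0.50, 0.10, 0.08, 0.06)
        steps = [abs(b - a) for a, b in zip(blockades, blockades[1:])]
        assert max(range(3), key=lambda i: steps[i]) == 0
        cal = PegCalibration((62, 200, 400, 600), (0.6, 0.9, 1.2, 1.5),
                             blockades)
        assert estimate_diameter_from_peg(cal) == (0.6, 0.9)

    def test_threshold_below_all_steps_warns(self):
        cal = PegCalibration((62, 200, 400), (0.6, 0.9, 1.2),
                             (0.10, 0.12, 0.14))
        with pytest.warns(UserWarning, match="jump threshold"):
            assert estimate_diameter_from_peg(cal, jump_threshold=0.5) == \
                (0.6, 1.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_diameter_from_peg(
                PegCalibration((62, 200), (0.6, 0.9), (0.1, 0.4)))

    def test_hydrodynamic_size_convention(self):
        assert float(peg_hydrodynamic_diameter(400)) == pytest.approx(1.2,
                                                                      abs=0.1)
        assert float(peg_hydrodynamic_diameter(600)) == pytest.approx(1.5,
                                                                      abs=0.1)
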