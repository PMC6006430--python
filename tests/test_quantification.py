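import math

import numpy as np
import pytest
from scipy import stats as sps

from rcaxon import SolutionState, build_axon_circuit, extract_features, simulate_transient
from rcaxon.quantification import (
    CalibrationCurve,
    CalibrationError,
    blank_corrected_a,
    build_calibration,
    compare_conditions,
    invert_calibration,
    percent_efflux,
)


class TestBlankCorrection:
    def test_stated_formula(self):
        assert blank_corrected_a(1.35, 1.20) == pytest.approx(0.15, rel=1e-12)

    def test_sample_equals_blank_gives_zero(self):
        assert blank_corrected_a(1.2, 1.2) == 0.0

    def test_invariant_to_common_voltage_rescaling(self, trace_source):
        """a/b is a ratio of deviations, so rescaling a trace's voltages leaves
        it unchanged; the blank-corrected a is then scale-invariant too."""
        from rcaxon.circuit import Trace

        tr = trace_source(1e-4)
        blank = trace_source(0.0)
        for scale in (0.5, 2.0, 7.3):
            scaled = Trace(tr.times, tr.voltages * scale, tr.dt)
            scaled_blank = Trace(blank.times, blank.voltages * scale, blank.dt)
            a_ref = blank_corrected_a(
                extract_features(tr).ratio, extract_features(blank).ratio
            )
            a_scaled = blank_corrected_a(
                extract_features(scaled).ratio, extract_features(scaled_blank).ratio
            )
            assert a_scaled == pytest.approx(a_ref, rel=1e-9)


class TestCalibrationCurve:
    def test_simulator_calibration_is_monotone_with_inverse(self, trace_source):
        """Calibration on the 0.025-0.5 mM trace family inverts its knots."""
        grid = [c * 1e-3 for c in (0.025, 0.04, 0.1, 0.2, 0.25, 0.5)]
        curve = build_calibration(grid, trace_source)
        assert np.all(np.diff(curve.a_values) > 0)
        for c, a in zip(curve.concentrations, curve.a_values):
            assert curve.invert(a) == pytest.approx(c, rel=1e-9)
            assert curve.a_of(c) == pytest.approx(a, rel=1e-9)

    def test_two_point_calibration_linear_interpolation(self):
        curve = CalibrationCurve(np.array([1e-5, 1e-4]), np.array([0.1, 0.5]))
        # midpoint in concentration maps to the a midpoint
        c_mid = 0.5 * (1e-5 + 1e-4)
        assert curve.a_of(c_mid) == pytest.approx(0.3, rel=1e-12)
        assert curve.invert(0.3) == pytest.approx(c_mid, rel=1e-12)

    def test_log_space_variant_interpolates_in_log_concentration(self):
        curve = CalibrationCurve(
            np.array([1e-5, 1e-4]), np.array([0.1, 0.5]), log_space=True
        )
        c_mid = 10 ** (0.5 * (math.log10(1e-5) + math.log10(1e-4)))
        assert curve.a_of(c_mid) == pytest.approx(0.3, rel=1e-12)
        assert curve.invert(0.3) == pytest.approx(c_mid, rel=1e-12)

    def test_non_monotone_points_rejected_with_diagnostics(self):
        with pytest.raises(CalibrationError, match="not strictly increasing"):
            CalibrationCurve(np.array([1e-5, 2e-5, 4e-5]), np.array([0.1, 0.3, 0.2]))

    def test_out_of_range_inversion_refused_then_clamped(self):
        curve = CalibrationCurve(np.array([1e-5, 1e-4]), np.array([0.1, 0.5]))
        with pytest.raises(CalibrationError, match="outside"):
            curve.invert(0.9)
        assert curve.invert(0.9, clamp=True) == 1e-4
        assert curve.invert(-0.1, clamp=True) == 0.0

    @pytest.mark.parametrize("log_space", [False, True])
    def test_toe_segment_linear_in_concentration(self, log_space):
        """Below the smallest knot both variants fall back to a linear toe
        anchored at the implicit (0, 0) blank knot."""
        curve = CalibrationCurve(
            np.array([2e-5, 1e-4]), np.array([0.2, 0.6]), log_space=log_space
        )
        assert curve.a_of(1e-5) == pytest.approx(0.1, rel=1e-12)
        assert curve.invert(0.1) == pytest.approx(1e-5, rel=1e-12)


class TestPercentEfflux:
    def test_triton_is_100_percent(self):
        assert percent_efflux(0.24e-3, 0.24e-3) == 100.0

    def test_zero_is_zero(self):
        assert percent_efflux(0.0, 0.24e-3) == 0.0

    def test_fig3_arithmetic(self):
        assert percent_efflux(0.02448e-3, 0.24e-3) == pytest.approx(10.2, rel=1e-12)

    def test_scale_invariance(self):
        assert percent_efflux(3.0, 12.0) == percent_efflux(3.0e-4, 12.0e-4)


class TestCompareConditions:
    def test_identical_groups(self):
        res = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(1.0, rel=1e-12)

    def test_welch_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_conditions(a, b, welch=True)
        # closed-form Welch statistic
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
        t = (ma - mb) / math.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p = 2 * sps.t.sf(abs(t), dof)
        assert res.t_statistic == pytest.approx(t, rel=1e-12)
        assert res.p_two_tailed == pytest.approx(p, rel=1e-12)

    def test_swap_antisymmetry(self):
        res_ab = compare_conditions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res_ba = compare_conditions([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res_ab.t_statistic == pytest.approx(-res_ba.t_statistic, rel=1e-12)
        assert res_ab.p_two_tailed == pytest.approx(res_ba.p_two_tailed, rel=1e-12)

    def test_degenerate_variance_fallback(self):
        res = compare_conditions([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_two_tailed == 1.0
        res2 = compare_conditions([2.0, 2.0], [3.0, 3.0])
        assert res2.degenerate and res2.p_two_tailed == 0.0


class TestEndToEndIdentity:
    @pytest.mark.parametrize("c_true_mM", [0.015, 0.05, 0.12, 0.2])
    def test_simulate_invert_roundtrip_within_2_percent(
        self, trace_source, calibration, c_true_mM
    ):
        """c -> trace -> a/b -> calibration inversion recovers c within 2%."""
        c_true = c_true_mM * 1e-3
        feats = extract_features(trace_source(c_true))
        a = blank_corrected_a(feats.ratio, calibration.blank_ratio)
        c_hat = invert_calibration(calibration, a)
        assert c_hat == pytest.approx(c_true, rel=2e-2)

    @pytest.mark.parametrize("c_true_mM", [0.01, 0.0245, 0.06, 0.12, 0.24])
    def test_percent_identity_within_half_point(self, trace_source, calibration, c_true_mM):
        """Noise-free percent efflux through the pipeline is within 0.5
        absolute points of the ground truth across the efflux range."""
        c_full = 0.24e-3
        c_true = c_true_mM * 1e-3

        def recover(c):
            feats = extract_features(trace_source(c))
            a = blank_corrected_a(feats.ratio, calibration.blank_ratio)
            return invert_calibration(calibration, a)

        recovered = percent_efflux(recover(c_true), recover(c_full))
        assert recovered == pytest.approx(100.0 * c_true / c_full, abs=0.5)
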