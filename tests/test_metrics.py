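"""Suppression indices, tuning-curve fits and decay-constant estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v1ssn.metrics import (
    PlaidDecomposition,
    SizeTuningCurve,
    double_gaussian_curve,
    fit_double_gaussian,
    fit_exponential_decay,
    fit_von_mises,
    modified_suppression_index,
    plaid_weight_fit,
    summation_field_size,
    suppression_index,
    surround_modulation_map,
    von_mises,
)

SIZES = np.array([0.5, 1.0, 1.5, 2.0, 4.0, 8.0, 16.0])


class TestSuppressionIndex:
    def test_definition(self):
        curve = SizeTuningCurve(SIZES, [10, 100, 80, 60, 40, 30, 21])
        assert suppression_index(curve) == pytest.approx(0.79)

    def test_monotone_curve_gives_zero(self):
        curve = SizeTuningCurve(SIZES, np.linspace(1, 7, 7))
        assert suppression_index(curve) == 0.0

    def test_complete_suppression(self):
        curve = SizeTuningCurve(SIZES, [1, 5, 3, 2, 1, 0.5, 0.0])
        assert suppression_index(curve) == 1.0

    def test_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            suppression_index(SizeTuningCurve(SIZES, np.zeros(7)))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.1, 100.0))
    def test_invariant_to_rescaling(self, scale):
        resp = np.array([5.0, 30.0, 22.0, 15.0, 11.0, 9.0, 8.0])
        si1 = suppression_index(SizeTuningCurve(SIZES, resp))
        si2 = suppression_index(SizeTuningCurve(SIZES, resp * scale))
        assert si1 == pytest.approx(si2)


class TestModifiedSuppressionIndex:
    @pytest.mark.parametrize("rc,rcs,expected", [
        (10, 12, -0.2), (10, 5, 0.5), (10, 10, 0.0),
    ])
    def test_examples(self, rc, rcs, expected):
        assert modified_suppression_index(rc, rcs) == pytest.approx(expected)

    def test_zero_center_rejected(self):
        with pytest.raises(ValueError):
            modified_suppression_index(0.0, 1.0)


class TestSummationFieldSize:
    def test_argmax_recovery(self):
        resp = np.array([1, 4, 9, 5, 3, 2, 1.5])
        assert summation_field_size(SizeTuningCurve(SIZES, resp)) == 1.5

    def test_tie_breaks_to_smallest(self):
        resp = np.array([1, 9, 9, 5, 3, 2, 1.5])
        assert summation_field_size(SizeTuningCurve(SIZES, resp)) == 1.0

    def test_double_gaussian_recovers_known_peak(self):
        s = np.linspace(0.4, 16, 12)
        true = (40.0, 0.8, 25.0, 2.5)
        rng = np.random.default_rng(0)
        resp = double_gaussian_curve(s, *true) * (1 + 0.02 * rng.standard_normal(s.size))
        curve = SizeTuningCurve(s, np.clip(resp, 0, None))
        fine = np.linspace(0.4, 16, 4000)
        truth_sfs = fine[np.argmax(double_gaussian_curve(fine, *true))]
        assert summation_field_size(curve, "double_gaussian") == pytest.approx(
            truth_sfs, abs=0.2)
        fit = fit_double_gaussian(curve)
        assert fit["r2"] > 0.95

    def test_unfittable_curve_flagged(self):
        curve = SizeTuningCurve(SIZES, np.zeros(7) + 0.0)
        assert fit_double_gaussian(curve) is None


class TestSurroundModulationMap:
    def test_row_minimum_is_zero_and_diag_argmin(self):
        offs = np.arange(-20.0, 21.0, 10.0)
        cs = np.ones((5, 5)) * 8.0
        np.fill_diagonal(cs, 2.0)
        co = np.full(5, 10.0)
        mod, most, mask = surround_modulation_map(cs, co, offs)
        assert np.allclose(mod.min(axis=1), 0.0)
        np.testing.assert_allclose(most, offs)
        assert mask.all()

    def test_flat_rows_tie_break_toward_zero_offset(self):
        offs = np.arange(-20.0, 21.0, 10.0)
        cs = np.ones((2, 5))
        co = np.ones(2)
        _, most, _ = surround_modulation_map(cs, co, offs)
        assert np.all(most == 0.0)

    def test_zero_center_rows_dropped(self):
        offs = np.arange(-10.0, 11.0, 10.0)
        cs = np.ones((3, 3))
        co = np.array([1.0, 0.0, 2.0])
        mod, most, mask = surround_modulation_map(cs, co, offs)
        assert mask.tolist() == [True, False, True]
        assert mod.shape == (2, 3)


class TestPlaidWeightFit:
    bins = np.arange(2.5, 180, 5.0)

    def _components(self):
        P1 = von_mises(self.bins, 1.0, 8.0, 3.0, 40.0)
        P2 = von_mises(self.bins, 1.0, 8.0, 3.0, 100.0)
        return P1, P2

    def test_exact_recovery(self):
        P1, P2 = self._components()
        fit = plaid_weight_fit(self.bins, P1, P2, 1.0 * P1 + 1.0 * P2, plaid_angle=60)
        assert not fit.missing
        assert fit.w1 == pytest.approx(1.0, abs=1e-6)
        assert fit.w2 == pytest.approx(1.0, abs=1e-6)

    def test_recovery_with_noise_matches_normal_equations(self):
        """Noise-free weights match a direct normal-equations solve to 1e-8;
        5% noise keeps recovery within 5%."""
        P1, P2 = self._components()
        y = 0.8 * P1 + 0.3 * P2
        fit = plaid_weight_fit(self.bins, P1, P2, y, plaid_angle=60)
        A = np.column_stack([von_mises(self.bins, *fit_von_mises(self.bins, P1)[0]),
                             von_mises(self.bins, *fit_von_mises(self.bins, P2)[0])])
        direct = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.w1 == pytest.approx(direct[0], abs=1e-8)
        assert fit.w2 == pytest.approx(direct[1], abs=1e-8)
        rng = np.random.default_rng(1)
        noisy = y * (1 + 0.05 * rng.standard_normal(y.size))
        fit_n = plaid_weight_fit(self.bins, P1, P2, noisy, plaid_angle=60)
        assert fit_n.w1 == pytest.approx(0.8, rel=0.05)
        assert fit_n.w2 == pytest.approx(0.3, rel=0.12)

    def test_zero_angle_degenerate(self):
        P1, _ = self._components()
        fit = plaid_weight_fit(self.bins, P1, P1, 2.0 * P1, plaid_angle=0)
        assert fit.degenerate
        assert fit.w1 == pytest.approx(2.0, abs=1e-6)
        assert fit.w2 == 0.0

    def test_unfittable_component_flagged_missing(self):
        flat = np.ones_like(self.bins)
        fit = plaid_weight_fit(self.bins, flat, flat, flat, plaid_angle=60)
        assert fit.missing


class TestExponentialDecayFit:
    def test_exact_recovery(self):
        t = np.arange(0.0, 50.0, 0.5)
        y = 3.0 * np.exp(-t / 10.0)
        assert fit_exponential_decay(t, y) == pytest.approx(10.0, abs=1e-6)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 60.0, 0.25)
        y = 5.0 * np.exp(-t / 8.0) * (1 + 0.05 * rng.standard_normal(t.size))
        assert fit_exponential_decay(t, np.clip(y, 1e-9, None)) == pytest.approx(
            8.0, rel=0.05)

    def test_constant_series_rejected(self):
        t = np.arange(0.0, 30.0, 1.0)
        with pytest.raises(ValueError):
            fit_exponential_decay(t, np.ones_like(t))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(np.array([0, 1, 2.0]), np.array([1, 0.5, 0.2]))

    def test_window_excludes_floor(self):
        """Points below 1% of the initial value (e.g. a noise floor) must not
        bias the fit."""
        t = np.arange(0.0, 120.0, 0.5)
        y = np.maximum(10.0 * np.exp(-t / 10.0), 0.05)
        assert fit_exponential_decay(t, y) == pytest.approx(10.0, abs=0.05)
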