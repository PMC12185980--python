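"""Rate dynamics: fixed points, convergence, current split, decay runs."""

import numpy as np
import pytest

from v1ssn.connectivity import ConnectivityParams, build_weights
from v1ssn.rate import (
    IntegrationError,
    RateParams,
    decay_protocol,
    decompose_currents,
    integrate_to_steady,
    rate_rhs,
)
from v1ssn.stimulus import StimulusSpec, render_input


@pytest.fixture(scope="module")
def zero_weights(tiny_map):
    return build_weights(tiny_map, ConnectivityParams().scaled(0.0), mode="dense")


class TestRateRHS:
    def test_zero_state_zero_drive_is_fixed_point(self, zero_weights):
        N = zero_weights.n
        dE, dI = rate_rhs(np.zeros(N), np.zeros(N), np.zeros(N), zero_weights)
        assert np.all(dE == 0) and np.all(dI == 0)

    def test_rectification_below_threshold(self, tiny_map):
        """With strongly negative net input the bracket clips to zero and the
        rate decays as -r/tau."""
        W = build_weights(tiny_map, mode="dense")
        N = W.n
        r = np.full(N, 2.0)
        drive = np.full(N, -1e3)
        p = RateParams()
        dE, dI = rate_rhs(r, r, drive, W, p)
        np.testing.assert_allclose(dE, -2.0 / p.tau_E)
        np.testing.assert_allclose(dI, -2.0 / p.tau_I)

    def test_nonfinite_state_rejected(self, zero_weights):
        N = zero_weights.n
        bad = np.zeros(N)
        bad[0] = np.nan
        with pytest.raises(IntegrationError):
            rate_rhs(bad, np.zeros(N), np.zeros(N), zero_weights)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RateParams(dt=5.0)  # > tau_I / 5
        with pytest.raises(ValueError):
            RateParams(n_E=0.5)


class TestIntegrateToSteady:
    def test_zero_drive_converges_to_zero(self, zero_weights):
        st = integrate_to_steady(np.zeros(zero_weights.n), zero_weights)
        assert st.converged
        assert np.all(st.rE == 0) and np.all(st.rI == 0)

    def test_uncoupled_power_law_fixed_point(self, zero_weights):
        """An isolated unit with I_ext = 10 settles at K * 10^n = 0.01*10^2.2."""
        drive = np.zeros(zero_weights.n)
        drive[5] = 10.0
        p = RateParams(tol=1e-9, T=4000.0)
        st = integrate_to_steady(drive, zero_weights, p)
        expected = 0.01 * 10.0**2.2
        assert st.converged
        assert st.rE[5] == pytest.approx(expected, abs=1e-6)
        assert st.rI[5] == pytest.approx(expected, abs=1e-6)

    def test_fixed_point_residual(self, small_bundle):
        """At an accepted steady state |r - K [I]_+^n| is below tolerance."""
        omap, W = small_bundle["map"], small_bundle["weights"]
        drive = render_input(small_bundle["stimuli"]["center_high"], omap)
        p = RateParams(tol=1e-7)
        st = integrate_to_steady(drive, W, p)
        assert st.converged
        dE, dI = rate_rhs(st.rE, st.rI, drive, W, p)
        scale = np.maximum(np.maximum(st.rE, st.rI), 1e-3)
        assert np.max(np.abs(dE) * p.tau_E / scale) < 1e-5
        assert np.max(np.abs(dI) * p.tau_I / scale) < 1e-5

    def test_halving_dt_changes_steady_state_little(self, small_bundle):
        omap, W = small_bundle["map"], small_bundle["weights"]
        c = small_bundle["center_cell"]
        drive = render_input(small_bundle["stimuli"]["center_high"], omap)
        st1 = integrate_to_steady(drive, W, RateParams(dt=1.0, tol=1e-8))
        st2 = integrate_to_steady(drive, W, RateParams(dt=0.5, tol=1e-8))
        assert st1.rE[c] == pytest.approx(st2.rE[c], rel=1e-3)
        assert st1.rI[c] == pytest.approx(st2.rI[c], rel=1e-3)

    def test_batch_matches_individual_runs(self, small_bundle):
        """Stimulus order cannot matter: every stimulus is integrated from
        zero rates, so batched and individual runs agree exactly."""
        omap, W = small_bundle["map"], small_bundle["weights"]
        d1 = render_input(small_bundle["stimuli"]["center_high"], omap)
        d2 = render_input(small_bundle["stimuli"]["small_high"], omap)
        batch = integrate_to_steady(np.column_stack([d1, d2]), W)
        solo1 = integrate_to_steady(d1, W)
        solo2 = integrate_to_steady(d2, W)
        np.testing.assert_allclose(batch.rE[:, 0], solo1.rE, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(batch.rE[:, 1], solo2.rE, rtol=1e-6, atol=1e-9)

    def test_runaway_network_raises(self, tiny_map):
        """Scaling all excitatory strengths far up destabilizes the circuit;
        the integrator reports divergence instead of returning garbage."""
        p = ConnectivityParams()
        import dataclasses

        strong = dataclasses.replace(p, J_EE_short=p.J_EE_short * 300,
                                     J_EE_long=p.J_EE_long * 300)
        W = build_weights(tiny_map, strong, mode="dense")
        drive = np.full(W.n, 40.0)
        with pytest.raises(IntegrationError):
            integrate_to_steady(drive, W, RateParams(T=500.0), max_dt_halvings=0)


class TestDecomposeCurrents:
    def test_zero_weights_all_external(self, zero_weights):
        drive = np.full(zero_weights.n, 7.0)
        st = integrate_to_steady(drive, zero_weights)
        dec = decompose_currents(st, drive, zero_weights, 3, "E")
        assert dec.I_exc_recurrent == 0 and dec.I_inh == 0
        assert dec.net == pytest.approx(7.0)
        assert dec.network_fraction == 0.0

    def test_batched_state_rejected(self, zero_weights):
        drive = np.zeros((zero_weights.n, 2))
        st = integrate_to_steady(drive, zero_weights)
        with pytest.raises(ValueError):
            decompose_currents(st, drive, zero_weights, 0, "E")


class TestDecayProtocol:
    def test_uncoupled_decay_recovers_cell_constants(self, zero_weights):
        """Without recurrence the decay constants equal tau_E and tau_I."""
        from v1ssn.metrics import fit_exponential_decay

        drive = np.zeros(zero_weights.n)
        drive[4] = 20.0
        # dt_record=0.01 keeps the Euler discretization bias of the decay
        # constant (-dt/ln(1 - dt/tau) - tau ~ dt/2) below the tolerance
        t, trE, trI, _ = decay_protocol(drive, zero_weights, cells=[4],
                                        t_post=60.0, dt_record=0.01)
        tauE = fit_exponential_decay(t, trE[:, 0], t_off=200.0)
        tauI = fit_exponential_decay(t, trI[:, 0], t_off=200.0)
        assert tauE == pytest.approx(10.0, abs=0.01)
        assert tauI == pytest.approx(6.67, abs=0.01)

    def test_requires_recorded_cells(self, zero_weights):
        with pytest.raises(ValueError):
            decay_protocol(np.zeros(zero_weights.n), zero_weights)
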