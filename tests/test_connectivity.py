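"""Connectivity kernels, weight construction and regime diagnostics."""

import numpy as np
import pytest
import scipy.sparse as sp

from v1ssn.connectivity import (
    ConnectivityParams,
    build_weights,
    orientation_kernel,
    regime_diagnostics,
    spatial_kernel_E,
    spatial_kernel_I,
    weight_vs_distance_profile,
)
from v1ssn.geometry import make_orientation_map, orientation_distance, torus_distance


class TestSpatialKernels:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 1.0), (3.0, 1.0), (6.0, np.exp(-0.5)),
    ])
    def test_e_kernel_plateau_and_tail(self, x, expected):
        assert spatial_kernel_E(x, sigma=3.0, L_o=3.0) == pytest.approx(expected)

    @pytest.mark.parametrize("x,sigma,expected", [
        (0.0, 2.0, 1.0), (2.0, 2.0, np.exp(-0.5)), (4.0, 2.0, np.exp(-2.0)),
        (6.0, 2.0, np.exp(-4.5)),
    ])
    def test_i_kernel_gaussian(self, x, sigma, expected):
        assert spatial_kernel_I(x, sigma) == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            spatial_kernel_E(1.0, sigma=0.0)
        with pytest.raises(ValueError):
            spatial_kernel_I(1.0, sigma=-1.0)

    def test_e_kernel_nonincreasing_beyond_plateau(self):
        x = np.linspace(0, 30, 500)
        y = spatial_kernel_E(x, sigma=6.0, L_o=3.0)
        assert np.all(np.diff(y) <= 1e-15)


class TestOrientationKernel:
    def test_normalized_at_zero(self):
        assert orientation_kernel(0.0, 0.2, 0.8, 55.0) == pytest.approx(1.0)
        assert orientation_kernel(0.0, 0.14, 0.86, 25.0) == pytest.approx(1.0)

    def test_closed_forms(self):
        assert orientation_kernel(90.0, 0.14, 0.86, 25.0) == pytest.approx(
            0.14 + 0.86 * np.exp(-(90.0**2) / (2 * 25.0**2)))
        assert orientation_kernel(55.0, 0.2, 0.8, 55.0) == pytest.approx(
            0.2 + 0.8 * np.exp(-0.5))


def naive_weights(omap, p):
    """Independent triple-loop oracle for the connection-strength rule."""
    grid = omap.grid
    n = grid.n_side
    N = grid.n_cells
    theta = omap.theta_flat
    W = {k: np.zeros((N, N)) for k in ("EE", "EI", "IE", "II")}
    for a in range(N):
        ai, aj = divmod(a, n)
        for b in range(N):
            bi, bj = divmod(b, n)
            d = torus_distance((ai, aj), (bi, bj), grid)
            dth = orientation_distance(theta[a], theta[b])
            q_short = p.A_short + p.B_short * np.exp(-dth**2 / (2 * p.sigma_ori_short**2))
            q_long = p.A_long + p.B_long * np.exp(-dth**2 / (2 * p.sigma_ori_long**2))
            if d < p.L_o:
                W["EE"][a, b] = p.J_EE_short * q_short
                W["IE"][a, b] = p.J_IE_short * q_short
            else:
                pe_EE = np.exp(-((d - p.L_o) ** 2) / (2 * p.sigma_EE**2)) if d > p.L_o else 1.0
                pe_IE = np.exp(-((d - p.L_o) ** 2) / (2 * p.sigma_IE**2)) if d > p.L_o else 1.0
                W["EE"][a, b] = p.J_EE_long * pe_EE * q_long
                W["IE"][a, b] = p.J_IE_long * pe_IE * q_long
            W["EI"][a, b] = p.J_EI * np.exp(-(d**2) / (2 * p.sigma_EI**2)) * q_short
            W["II"][a, b] = p.J_II * np.exp(-(d**2) / (2 * p.sigma_II**2)) * q_short
            if a == b and not p.include_autapses:
                W["EE"][a, b] = 0.0
                W["II"][a, b] = 0.0
    return W


class TestBuildWeights:
    @pytest.mark.parametrize("autapses", [True, False])
    def test_oracle_equivalence_on_6x6(self, tiny_map, autapses):
        """Dense and sparse builds match the naive triple-loop oracle
        entry-for-entry (sparse only drops spatial factors below cutoff)."""
        params = ConnectivityParams(include_autapses=autapses)
        expected = naive_weights(tiny_map, params)
        dense = build_weights(tiny_map, params, mode="dense")
        for name, block in dense.blocks().items():
            np.testing.assert_allclose(block, expected[name], atol=1e-12)
        sparse = build_weights(tiny_map, params, mode="sparse")
        for name, block in sparse.blocks().items():
            diff = np.abs(block.toarray() - expected[name])
            # on a 6x6 torus every distance is within the sparse cutoffs
            assert diff.max() < 1e-12

    def test_same_site_weights(self, tiny_map):
        dense = build_weights(tiny_map, ConnectivityParams(), mode="dense")
        np.testing.assert_allclose(np.diag(dense.W_EE), 0.072, atol=1e-12)
        np.testing.assert_allclose(np.diag(dense.W_EI), 0.0528, atol=1e-12)
        no_aut = build_weights(tiny_map, ConnectivityParams(include_autapses=False),
                               mode="dense")
        assert np.all(np.diag(no_aut.W_EE) == 0)
        assert np.all(np.diag(no_aut.W_II) == 0)
        np.testing.assert_allclose(np.diag(no_aut.W_IE), 0.06, atol=1e-12)

    def test_long_range_pair_value_on_flat_map(self):
        """E->I weight at 10 grid intervals with matched orientations equals
        J_long * exp(-(10-3)^2 / (2*36))."""
        omap = make_orientation_map(seed=0)
        omap.theta[:] = 42.0  # flatten the map: all orientation factors are 1
        W = build_weights(omap)
        grid = omap.grid
        a = grid.cell_index(30, 30)
        b = grid.cell_index(40, 30)
        expected = 0.036 * np.exp(-((10 - 3) ** 2) / (2 * 6.0**2))
        assert W.W_IE[a, b] == pytest.approx(expected, rel=1e-12)
        assert W.W_IE[b, a] == pytest.approx(expected, rel=1e-12)

    def test_zero_strengths_give_zero_weights(self, tiny_map):
        W = build_weights(tiny_map, ConnectivityParams().scaled(0.0), mode="dense")
        for block in W.blocks().values():
            assert np.all(block == 0)

    def test_dense_mode_memory_guard(self, default_map):
        with pytest.raises(MemoryError):
            build_weights(default_map, mode="dense")

    def test_save_load_roundtrip(self, tiny_map, tmp_path):
        from v1ssn.connectivity import WeightSet

        W = build_weights(tiny_map)
        W.save(tmp_path / "w")
        W2 = WeightSet.load(tmp_path / "w")
        for name in ("EE", "EI", "IE", "II"):
            a = W.blocks()[name].toarray()
            b = W2.blocks()[name].toarray()
            np.testing.assert_allclose(a, b, atol=0)
        assert np.array_equal(W.omap.theta, W2.omap.theta)


class TestRegimeDiagnostics:
    def test_zero_and_linearity(self, tiny_map):
        W0 = build_weights(tiny_map, ConnectivityParams().scaled(0.0), mode="dense")
        d0 = regime_diagnostics(W0)
        assert d0.omega_E == 0 and d0.omega_I == 0
        W1 = build_weights(tiny_map, mode="dense")
        W2 = build_weights(tiny_map, ConnectivityParams().scaled(2.0), mode="dense")
        d1, d2 = regime_diagnostics(W1), regime_diagnostics(W2)
        assert d2.omega_E == pytest.approx(2 * d1.omega_E)
        assert d2.omega_I == pytest.approx(2 * d1.omega_I)

    def test_default_regime_signs(self, default_weights):
        """The standard parameters put the network in the saturating SSN
        regime: Omega_E < 0 < Omega_I."""
        d = regime_diagnostics(default_weights)
        assert d.omega_E < 0
        assert d.omega_I > 0
        assert d.omega_E < d.omega_I


class TestWeightProfile:
    def test_profile_zero_distance_and_bump(self, default_weights):
        """The 0-mm bin reports the same-site E->E kernel value; the E->I
        profile has a secondary local maximum near 1 mm (the orientation-map
        period) exceeding its value at 0.6 mm."""
        prof = weight_vs_distance_profile(default_weights, max_mm=1.6, bin_mm=0.05)
        centers, mean_EE = prof["EE"]
        assert mean_EE[0] == pytest.approx(0.072, rel=1e-6)
        centers, mean_IE = prof["IE"]
        window = (centers > 0.7) & (centers < 1.25)
        bump_val = np.nanmax(mean_IE[window])
        bump_mm = centers[window][int(np.nanargmax(mean_IE[window]))]
        dip = (centers > 0.45) & (centers < bump_mm)
        assert bump_val > np.nanmin(mean_IE[dip])

    def test_zero_weights_flat_profile(self, tiny_map):
        W = build_weights(tiny_map, ConnectivityParams().scaled(0.0))
        prof = weight_vs_distance_profile(W, max_mm=0.3, bin_mm=0.05)
        for _, (centers, mean) in prof.items():
            assert np.nanmax(np.abs(mean)) == 0
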