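import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octoprops import (
    AScanProfile,
    DepthGrid,
    LayerSpec,
    LayerWindow,
    PhantomSpec,
    PhaseFunction,
    init_R,
    layer_R_fit,
    layer_mu_fit,
    mean_R,
    phase_R,
    phase_g,
    simulate_aline,
    vermeer_mu,
)
from octoprops.forward_model import irradiance

from conftest import make_homogeneous


class TestVermeerMu:
    def test_exact_for_constant_R(self, homogeneous):
        """The depth-resolved baseline is exact when R is constant."""
        phantom, grid, aline = homogeneous
        mu0 = vermeer_mu(aline)
        sl = grid.window(0.2, 2.8)
        assert np.allclose(mu0[sl], 2.0, rtol=1e-4)

    def test_bias_pattern_from_R_step(self):
        """Equal mu, R stepping up at the interface: biased above, exact
        below (the error depends only on R variation below the depth)."""
        ph = PhantomSpec(
            0.1,
            (LayerSpec(0.5, 2.0, 0.004), LayerSpec(math.inf, 2.0, 0.008)),
            beta_L0=1.0,
        )
        grid = DepthGrid(0, 0.001, 3000)
        aline = simulate_aline(ph, grid)
        mu0 = vermeer_mu(aline)
        above = grid.window(0.15, 0.55)
        below = grid.window(0.7, 2.8)
        assert np.all(mu0[above] < 2.0)  # underestimates above a step up
        assert np.allclose(mu0[below], 2.0, rtol=1e-4)

    def test_zero_input_warns_and_zeroes(self):
        grid = DepthGrid(0, 0.001, 100)
        aline = AScanProfile(grid, np.zeros(100))
        with pytest.warns(UserWarning):
            mu0 = vermeer_mu(aline)
        assert np.allclose(mu0, 0.0)


class TestInitR:
    def test_inverts_homogeneous_fixture(self, homogeneous):
        phantom, grid, aline = homogeneous
        mu = phantom.mu_at(grid.depths)
        R0 = init_R(aline, mu, phantom.beta_L0)
        sl = grid.window(0.2, 2.8)
        assert np.allclose(R0[sl], 0.005, rtol=1e-4)

    def test_inverts_phantom2_with_true_mu(self, phantom2, grid2, phantom2_aline):
        mu = phantom2.mu_at(grid2.depths)
        R0 = init_R(phantom2_aline, mu, phantom2.beta_L0)
        edges = list(phantom2.interfaces) + [grid2.z_end]
        for i, layer in enumerate(phantom2.layers):
            sl = grid2.window(edges[i] + 0.005, edges[i + 1] - 0.005)
            assert np.allclose(R0[sl], layer.R, rtol=1e-3)

    def test_initialization_flattens_R(self, phantom2, grid2, phantom2_aline):
        """With the baseline mu (not the truth) the initialisation comes out
        nearly constant — flatter than the true layered profile."""
        mu0 = vermeer_mu(phantom2_aline)
        R0 = init_R(phantom2_aline, mu0, phantom2.beta_L0)
        sl = grid2.window(0.2, 2.8)
        cv_R0 = np.nanstd(R0[sl]) / np.nanmean(R0[sl])
        true_R = phantom2.R_at(grid2.depths)[sl]
        cv_true = np.std(true_R) / np.mean(true_R)
        assert cv_R0 < 0.1 * cv_true

    def test_zero_mu_everywhere_is_error(self, phantom2_aline):
        with pytest.raises(ValueError):
            init_R(phantom2_aline, np.zeros(phantom2_aline.grid.n), 1.0)

    def test_beta_l0_must_be_positive(self, phantom2_aline):
        with pytest.raises(ValueError):
            init_R(phantom2_aline, np.ones(phantom2_aline.grid.n), 0.0)


class TestMeanR:
    def test_homogeneous(self, homogeneous):
        phantom, grid, aline = homogeneous
        assert mean_R(aline, phantom.beta_L0) == pytest.approx(0.005, rel=1e-4)

    def test_zero_profile(self):
        grid = DepthGrid(0, 0.001, 100)
        assert mean_R(AScanProfile(grid, np.zeros(100)), 1.0) == 0.0

    def test_phantom2_weighted_mean(self, phantom2):
        """R~ equals the irradiance-weighted average of R(z) (offset grid:
        boundaries at interval midpoints)."""
        grid2 = DepthGrid(0.0005, 0.001, 3000)
        phantom2_aline = simulate_aline(phantom2, grid2)
        rt = mean_R(phantom2_aline, phantom2.beta_L0)
        Rs = [l.R for l in phantom2.layers]
        assert min(Rs) < rt < max(Rs)
        # brute-force weighted mean oracle: weights -beta dL over each layer
        bl = irradiance(phantom2, grid2)
        R = np.nan_to_num(phantom2.R_at(grid2.depths))
        dL = -np.diff(bl)
        oracle = float(np.sum(R[1:] * dL)) / phantom2.beta_L0
        # remaining weight beyond the grid belongs to the bottom layer
        oracle += phantom2.layers[-1].R * bl[-1] / phantom2.beta_L0
        assert rt == pytest.approx(oracle, rel=1e-3)


class TestLayerFits:
    def test_exact_slope(self, homogeneous):
        _, grid, aline = homogeneous
        assert layer_mu_fit(aline, LayerWindow(0.3, 1.0)) == pytest.approx(
            2.0, abs=1e-6
        )

    def test_straddling_window_is_between(self):
        # R chosen so the intensity is continuous at the interface and only
        # the decay rate changes
        ph = PhantomSpec(
            0.0,
            (LayerSpec(0.5, 1.0, 0.006), LayerSpec(math.inf, 3.0, 0.002)),
            beta_L0=1.0,
        )
        grid = DepthGrid(0, 0.001, 2000)
        aline = simulate_aline(ph, grid)
        mu = layer_mu_fit(aline, LayerWindow(0.3, 0.7))
        assert 1.0 < mu < 3.0

    def test_window_too_small(self, homogeneous):
        _, _, aline = homogeneous
        with pytest.raises(ValueError):
            layer_mu_fit(aline, LayerWindow(0.3, 0.303))

    def test_layer_R_recovers_model_R(self, homogeneous):
        phantom, grid, aline = homogeneous
        window = LayerWindow(0.3, 1.0)
        bl_at_z1 = float(irradiance(phantom, grid)[grid.index_of(window.z1)])
        r = layer_R_fit(aline, window, mu_g=2.0, beta_L_at_z1=bl_at_z1)
        assert r == pytest.approx(0.005, rel=1e-4)

    def test_layer_R_literal_convention_doubles(self, homogeneous):
        """The literal window formula carries a leading factor 2 that, on
        this intensity convention, returns twice the model R."""
        phantom, grid, aline = homogeneous
        window = LayerWindow(0.3, 1.0)
        bl_at_z1 = float(irradiance(phantom, grid)[grid.index_of(window.z1)])
        r = layer_R_fit(aline, window, 2.0, bl_at_z1, convention="literal")
        assert r == pytest.approx(0.010, rel=1e-4)

    def test_invalid_mu(self, homogeneous):
        _, _, aline = homogeneous
        with pytest.raises(ValueError):
            layer_R_fit(aline, LayerWindow(0.3, 1.0), 0.0, 1.0)


class TestPhaseFunctions:
    def test_isotropic_R_closed_form(self):
        """Backward-cone solid-angle fraction (1 - sqrt(1 - NA^2)) / 2."""
        na = 0.05
        expected = (1 - math.sqrt(1 - na * na)) / 2
        assert phase_R(PhaseFunction.isotropic(), na) == pytest.approx(
            expected, abs=1e-9 * expected + 1e-15
        )

    def test_full_hemisphere_limit(self):
        na = 0.999999
        expected = (1 - math.sqrt(1 - na * na)) / 2
        assert phase_R(PhaseFunction.isotropic(), na) == pytest.approx(
            expected, rel=1e-6
        )

    def test_forward_only_scattering_collects_nothing(self):
        fwd = PhaseFunction(
            gamma=lambda t: np.exp(-((np.asarray(t) / 0.05) ** 2))
        )
        assert phase_R(fwd, 0.05) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.01, max_value=0.5),
           st.floats(min_value=0.01, max_value=0.49))
    def test_monotone_in_na(self, na, dna):
        pf = PhaseFunction.henyey_greenstein(0.6)
        assert phase_R(pf, min(na + dna, 0.99)) >= phase_R(pf, na) - 1e-12

    def test_isotropic_g_is_zero(self):
        assert phase_g(PhaseFunction.isotropic()) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("g", [-0.5, 0.3, 0.9, 0.98])
    def test_hg_mean_cosine_identity(self, g):
        assert phase_g(PhaseFunction.henyey_greenstein(g)) == pytest.approx(
            g, abs=1e-6
        )

    def test_forward_delta_gives_unity(self):
        fwd = PhaseFunction(
            gamma=lambda t: np.exp(-((np.asarray(t) / 0.01) ** 2))
        )
        assert phase_g(fwd) == pytest.approx(1.0, abs=1e-3)
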