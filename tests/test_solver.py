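import math

import numpy as np
import pytest

from octoprops import (
    BScan,
    DepthGrid,
    IterationConfig,
    LayerSpec,
    PhantomSpec,
    fuzzy_process_R,
    simulate_aline,
    solve,
    solve_bscan,
    update_mu,
    vermeer_mu,
)

from conftest import make_homogeneous


def bruteforce_two_step_segments(R, thr_factor, dz):
    """Independent segmentation oracle for a profile with one known step:
    the backward log-difference exceeds the threshold only at the step."""
    trace = np.log(R)
    d = np.abs(np.diff(trace, prepend=trace[0])) / dz
    thr = thr_factor * d.mean()
    return np.nonzero(d > thr)[0]


class TestFuzzyProcessing:
    def test_constant_profile_single_segment(self):
        R = np.full(50, 0.005)
        pc, segs = fuzzy_process_R(R, 0.001)
        assert len(segs) == 1
        assert np.allclose(pc, 0.005)

    def test_two_step_profile(self):
        rng = np.random.default_rng(0)
        R = np.concatenate([np.full(60, 0.005), np.full(60, 0.007)])
        R = R + rng.uniform(-1e-5, 1e-5, R.size)
        pc, segs = fuzzy_process_R(R, 0.001, 4.5)
        assert len(segs) == 2
        # the detected breakpoint matches the independent oracle
        oracle = bruteforce_two_step_segments(R, 4.5, 0.001)
        assert segs[1][0] in oracle
        assert np.mean(pc[:55]) == pytest.approx(0.005, abs=1e-5)
        assert np.mean(pc[65:]) == pytest.approx(0.007, abs=1e-5)

    def test_large_factor_misses_the_step(self):
        """An overlarge threshold factor merges the layers, the known
        failure mode of too coarse fuzzy processing."""
        rng = np.random.default_rng(0)
        R = np.concatenate([np.full(50, 0.005), np.full(50, 0.007)])
        R = R + rng.uniform(-1e-5, 1e-5, R.size)
        _, segs = fuzzy_process_R(R, 0.001, 80.0)
        assert len(segs) == 1

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            fuzzy_process_R(np.array([0.1, 0.2]), 0.001)

    def test_breakpoints_join_deeper_segment(self):
        R = np.concatenate([np.full(40, 0.004), np.full(40, 0.008)])
        pc, segs = fuzzy_process_R(R, 0.001, 4.5)
        # the step pixel carries the deeper segment's mean
        assert pc[40] == pytest.approx(0.008, abs=1e-12)


class TestUpdateMu:
    def test_constant_R_equals_baseline(self, phantom2, phantom2_aline):
        """With one segment the coupled system degenerates to the
        depth-resolved baseline — the R division cancels exactly."""
        mu0 = vermeer_mu(phantom2_aline)
        R = np.full(phantom2_aline.grid.n, 0.006)
        cfg = IterationConfig()
        out = update_mu(phantom2_aline, R, mu0, cfg)
        sl = phantom2_aline.values > 0
        assert np.allclose(out[sl], mu0[sl], rtol=1e-12)

    def test_true_R_recovers_true_mu(self, phantom2):
        # offset grid: interfaces at interval midpoints, so the discrete
        # integrals see the jumps symmetrically
        grid = DepthGrid(0.0005, 0.001, 3000)
        aline = simulate_aline(phantom2, grid)
        mu0 = vermeer_mu(aline)
        R = phantom2.R_at(grid.depths)
        R_full = np.where(np.isnan(R), 1.0, R)
        out = update_mu(aline, R_full, mu0, IterationConfig())
        edges = list(phantom2.interfaces) + [grid.z_end]
        for i, layer in enumerate(phantom2.layers):
            sl = grid.window(edges[i] + 0.01, edges[i + 1] - 0.05)
            assert np.allclose(out[sl], layer.mu, rtol=1e-3)

    def test_correction_bias_sign_matches_step_sign(self):
        """A downstream R step biases the bracket in the step's direction."""
        for r2, expect_up in ((0.008, True), (0.002, False)):
            ph = PhantomSpec(
                0.1,
                (LayerSpec(0.5, 2.0, 0.004), LayerSpec(math.inf, 2.0, r2)),
                beta_L0=1.0,
            )
            grid = DepthGrid(0, 0.001, 3000)
            aline = simulate_aline(ph, grid)
            mu0 = vermeer_mu(aline)
            R = np.nan_to_num(ph.R_at(grid.depths), nan=1.0)
            cfg = IterationConfig(mode="correction", C=0.01, D=100.0)
            out = update_mu(aline, R, mu0, cfg, mu_k=mu0)
            sl = grid.window(0.15, 0.55)
            if expect_up:
                assert np.mean(out[sl]) > np.mean(mu0[sl])
            else:
                assert np.mean(out[sl]) < np.mean(mu0[sl])

    def test_modes_agree_on_two_layer_fixture(self):
        """Both update rules approximate the same correction; at interior
        depths (away from the surface and the interface) they agree within
        5% for a 50% backscattering step."""
        ph = PhantomSpec(
            0.1,
            (LayerSpec(0.5, 1.5, 0.004), LayerSpec(math.inf, 1.5, 0.006)),
            beta_L0=1.0,
        )
        grid = DepthGrid(0, 0.001, 3000)
        aline = simulate_aline(ph, grid)
        mu0 = vermeer_mu(aline)
        R = np.nan_to_num(ph.R_at(grid.depths), nan=1.0)
        ratio = update_mu(aline, R, mu0, IterationConfig(mode="ratio"))
        corr = update_mu(aline, R, mu0, IterationConfig(mode="correction"),
                         mu_k=mu0)
        interior = np.ones(grid.n, bool)
        interior[: grid.index_of(0.13)] = False
        interior[grid.index_of(0.57):grid.index_of(0.63)] = False
        interior[grid.index_of(2.9):] = False
        assert np.allclose(ratio[interior], corr[interior], rtol=0.05)

    def test_nonpositive_R_on_support_rejected(self, phantom2_aline):
        mu0 = vermeer_mu(phantom2_aline)
        with pytest.raises(ValueError):
            update_mu(phantom2_aline, np.zeros(phantom2_aline.grid.n), mu0,
                      IterationConfig())


class TestSolve:
    def test_constant_R_converges_immediately(self, homogeneous):
        """Constant backscattering is the degenerate fixed point: one loop,
        attenuation equal to the baseline."""
        phantom, grid, aline = homogeneous
        state = solve(aline, phantom.beta_L0)
        assert state.k == 1
        assert state.stop_reason == "converged"
        mu0 = vermeer_mu(aline)
        assert np.allclose(state.mu_k, mu0, rtol=1e-6, atol=1e-12)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            IterationConfig(E=0)
        with pytest.raises(ValueError):
            IterationConfig(A=2.0)
        with pytest.raises(ValueError):
            IterationConfig(mode="bogus")

    def test_phantom2_default_recovery(self, phantom2, grid2, phantom2_aline):
        """Per-layer means of mu and R land within 10% of the layer truth
        with default settings (the headline recovery property)."""
        state = solve(phantom2_aline, phantom2.beta_L0)
        edges = list(phantom2.interfaces) + [grid2.z_end]
        for i, layer in enumerate(phantom2.layers):
            sl = grid2.window(edges[i] + 0.025, edges[i + 1] - 0.025)
            assert np.mean(state.mu_k[sl]) == pytest.approx(layer.mu, rel=0.10)
            assert np.nanmean(state.R_k[sl]) == pytest.approx(layer.R, rel=0.10)
        assert state.k <= 4  # a few loops suffice on clean data

    def test_emitted_state_satisfies_constraints(self, phantom2, grid2,
                                                 phantom2_aline):
        cfg = IterationConfig()
        state = solve(phantom2_aline, phantom2.beta_L0, cfg)
        assert state.k <= cfg.E
        sup = phantom2_aline.values > 0
        R = state.R_k[sup]
        R = R[np.isfinite(R)]
        assert np.all((R > 0) & (R < 1))
        assert np.all(R > cfg.A * state.R_tilde)
        assert np.all(R < cfg.B * state.R_tilde)
        mu0 = state.mu0[sup]
        ratio = state.mu_k[sup][mu0 > 0] / mu0[mu0 > 0]
        assert np.all(ratio >= cfg.C - 1e-12)
        assert np.all(ratio <= cfg.D + 1e-12)
        assert len(state.history) == state.k

    def test_history_is_recorded(self, phantom2, phantom2_aline):
        state = solve(phantom2_aline, phantom2.beta_L0)
        assert all(np.isfinite(h) for h in state.history)


class TestSolveBscan:
    def test_identical_columns_identical_maps(self, phantom2, phantom2_aline):
        grid = phantom2_aline.grid
        values = np.tile(phantom2_aline.values.reshape(-1, 1), (1, 3))
        bscan = BScan(grid, values)
        mu_map, R_map, states = solve_bscan(bscan, phantom2.beta_L0)
        assert np.array_equal(mu_map[:, 0], mu_map[:, 1])
        assert np.array_equal(mu_map[:, 0], mu_map[:, 2])
        assert len(states) == 3

    def test_zero_column_falls_back(self, phantom2, phantom2_aline):
        grid = phantom2_aline.grid
        values = np.stack([phantom2_aline.values,
                           np.zeros(grid.n),
                           phantom2_aline.values], axis=1)
        with pytest.warns(UserWarning):
            mu_map, R_map, states = solve_bscan(BScan(grid, values),
                                                phantom2.beta_L0)
        assert states[1].stop_reason.startswith("error")
        assert np.allclose(mu_map[:, 1], 0.0)
        # neighbours unaffected
        assert np.array_equal(mu_map[:, 0], mu_map[:, 2])
        assert not np.allclose(mu_map[:, 0], 0.0)
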