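import numpy as np
import pytest

from octoprops import (
    AScanProfile,
    BScan,
    CalibrationPair,
    DepthGrid,
    NoiseFloorCrossingError,
    PreprocessConfig,
    PsfModel,
    attach_tail_from_fit,
    average_bscans,
    calibrate_psf,
    extrapolate_tail,
    fit_noise_floor,
    from_db,
    psf_apply,
    psf_correct,
)

from conftest import make_homogeneous


def make_bscan(values, dz=0.002):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return BScan(DepthGrid(0.0, dz, values.shape[0]), values)


class TestAveraging:
    def test_mean_of_identical_is_identity(self):
        b = make_bscan(np.arange(12.0).reshape(6, 2))
        out = average_bscans([b, b, b])
        assert np.array_equal(out.values, b.values)

    def test_mean_of_two(self):
        a = make_bscan(np.zeros((4, 2)))
        b = make_bscan(np.full((4, 2), 2.0))
        assert np.allclose(average_bscans([a, b]).values, 1.0)

    def test_geometry_mismatch(self):
        a = make_bscan(np.zeros((4, 2)))
        b = make_bscan(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            average_bscans([a, b])

    def test_speckle_variance_reduction(self):
        """Averaging 5 exponential-speckle frames cuts the variance ~5x."""
        rng = np.random.default_rng(42)
        n = 10_000
        base = np.full((n, 1), 3.0)
        frames = [
            make_bscan(base * rng.exponential(1.0, size=(n, 1))) for _ in range(5)
        ]
        single_var = np.var(frames[0].values)
        mean_var = np.var(average_bscans(frames, 5).values)
        assert mean_var == pytest.approx(single_var / 5, rel=0.3)


class TestPsf:
    def test_focus_is_unity(self):
        psf = PsfModel(z_R=0.3, z_f=1.0)
        assert psf.h(1.0) == pytest.approx(1.0)

    def test_one_rayleigh_length_halves(self):
        psf = PsfModel(z_R=0.3, z_f=1.0)
        assert psf.h(1.3) == pytest.approx(0.5)
        b = make_bscan(np.ones((3, 1)), dz=0.65)
        corrected = psf_correct(b, psf)
        assert corrected.values[2, 0] == pytest.approx(2.0)

    def test_apply_then_correct_is_identity(self):
        rng = np.random.default_rng(1)
        b = make_bscan(rng.random((200, 4)) + 0.1)
        psf = PsfModel(z_R=0.15, z_f=0.2)
        back = psf_correct(psf_apply(b, psf), psf)
        assert np.allclose(back.values, b.values, rtol=1e-9)

    def test_invalid_rayleigh_length(self):
        with pytest.raises(ValueError):
            PsfModel(z_R=0.0)


def synth_calibration_pair(z_R, z_f, delta=0.2, dz=0.002, n=400, n_cols=4,
                           noise=0.0, seed=0):
    grid = DepthGrid(0.0, dz, n)
    psf = PsfModel(z_R=z_R, z_f=z_f)
    base = np.exp(-(((grid.depths - 0.6) / 0.15) ** 2)) * 100 + 1.0
    shift = int(round(delta / dz))
    deeper = np.concatenate([np.full(shift, 1.0), base[:-shift]])
    rng = np.random.default_rng(seed)
    v1 = np.tile((base * psf.h(grid.depths)).reshape(-1, 1), (1, n_cols))
    v2 = np.tile((deeper * psf.h(grid.depths)).reshape(-1, 1), (1, n_cols))
    if noise:
        v1 = v1 * (1 + noise * rng.standard_normal(v1.shape))
        v2 = v2 * (1 + noise * rng.standard_normal(v2.shape))
    return CalibrationPair(BScan(grid, v1), BScan(grid, v2), delta)


ZR_GRID = np.round(np.arange(0.05, 0.501, 0.05), 6)
ZF_GRID = np.round(np.arange(0.0, 1.501, 0.1), 6)


class TestCalibration:
    def test_exact_recovery_on_grid(self):
        pair = synth_calibration_pair(z_R=0.25, z_f=0.8)
        psf = calibrate_psf(pair, ZR_GRID, ZF_GRID)
        assert (psf.z_R, psf.z_f) == (0.25, 0.8)

    def test_degenerate_pair_rejected(self):
        pair = synth_calibration_pair(z_R=0.25, z_f=0.8)
        with pytest.raises(ValueError):
            CalibrationPair(pair.image1, pair.image1, 0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_reimplementation(self, seed):
        """The search IS exhaustive: an independent double loop must agree."""
        rng = np.random.default_rng(seed)
        z_R = float(rng.choice(ZR_GRID))
        z_f = float(rng.choice(ZF_GRID))
        pair = synth_calibration_pair(z_R=z_R, z_f=z_f, noise=0.02, seed=seed)
        psf = calibrate_psf(pair, ZR_GRID, ZF_GRID)

        grid = pair.image1.grid
        shift = int(round(pair.delta_z / grid.dz))
        a = pair.image1.values[: grid.n - shift]
        b = pair.image2.values[shift:]
        za = grid.depths[: grid.n - shift]
        zb = za + pair.delta_z
        best = (np.inf, None, None)
        for zr in ZR_GRID:
            for zf in ZF_GRID:
                h1 = 1.0 / (((za - zf) / zr) ** 2 + 1.0)
                h2 = 1.0 / (((zb - zf) / zr) ** 2 + 1.0)
                cost = np.sum(np.abs(a / h1[:, None] - b / h2[:, None]))
                if cost < best[0]:
                    best = (cost, zr, zf)
        assert (psf.z_R, psf.z_f) == (best[1], best[2])

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_one_percent_noise_within_one_step(self, seed):
        pair = synth_calibration_pair(z_R=0.25, z_f=0.8, noise=0.01, seed=seed)
        psf = calibrate_psf(pair, ZR_GRID, ZF_GRID)
        assert abs(psf.z_R - 0.25) <= 0.05 + 1e-12
        assert abs(psf.z_f - 0.8) <= 0.1 + 1e-12


class TestNoiseFloor:
    def grid(self, n=3000):
        return DepthGrid(0.0, 0.001, n)

    def test_pure_exponential_recovery(self):
        grid = self.grid()
        aline = AScanProfile(grid, 1e7 * np.exp(-2 * 2.0 * grid.depths))
        fit = fit_noise_floor(aline)
        assert fit.mu_tilde == pytest.approx(2.0, abs=1e-6)
        assert fit.z_nf0 < fit.z_nf1

    def test_profile_above_thresholds_is_error(self):
        grid = self.grid(500)
        aline = AScanProfile(grid, np.full(500, 1e9))
        with pytest.raises(NoiseFloorCrossingError):
            fit_noise_floor(aline)

    def test_floor_contaminated_fixture(self):
        """A constant 50 dB floor: the crossing lands at the floor level
        and the fitted decay matches the layer attenuation."""
        _, grid, aline = make_homogeneous(mu=2.5, R=0.005, beta_L0=5e11)
        floor = float(from_db(50.0))
        noisy = AScanProfile(grid, np.clip(aline.values, 0, None) + floor)
        fit = fit_noise_floor(noisy)
        assert fit.mu_tilde == pytest.approx(2.5, rel=0.05)
        assert fit.floor_level == pytest.approx(floor, rel=0.05)
        # the crossing sits where the signal has decayed to the floor level
        signal_at_floor = np.argmin(
            np.abs(np.clip(aline.values, 0, None)[500:] - floor)
        )
        assert abs(grid.depths[500 + signal_at_floor] - fit.z_nf1) < 0.3

    def test_extrapolation_self_consistency(self):
        grid = self.grid()
        values = 1e7 * np.exp(-2 * 2.0 * grid.depths)
        aline = AScanProfile(grid, values)
        fit = fit_noise_floor(aline)
        out = extrapolate_tail(aline, fit)
        assert np.allclose(out.values, values, rtol=1e-5)
        assert out.tail is not None
        # analytic remainder of A exp(-2 mu z) from z_end
        expected = fit.prefactor * np.exp(-2 * fit.mu_tilde * grid.z_end) / (
            2 * fit.mu_tilde
        )
        assert out.tail.integral() == pytest.approx(expected, rel=1e-9)

    def test_flat_floor_replaced_by_decay(self):
        _, grid, aline = make_homogeneous(mu=2.5, R=0.005, beta_L0=5e11)
        floor = float(from_db(50.0))
        noisy = AScanProfile(grid, np.clip(aline.values, 0, None) + floor)
        fit = fit_noise_floor(noisy)
        out = extrapolate_tail(noisy, fit)
        beyond = grid.depths > fit.z_nf1 + 0.1
        assert np.all(np.diff(out.values[beyond]) < 0)

    def test_attach_tail_from_fit(self):
        grid = self.grid(1000)
        aline = AScanProfile(grid, 5.0 * np.exp(-2 * 1.5 * grid.depths))
        out = attach_tail_from_fit(aline)
        assert out.tail.mu == pytest.approx(1.5, rel=1e-3)


class TestPreprocessConfig:
    def test_threshold_ordering(self):
        with pytest.raises(ValueError):
            PreprocessConfig(floor_db=58, start_db=50)

    def test_navg_positive(self):
        with pytest.raises(ValueError):
            PreprocessConfig(n_average=0)
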