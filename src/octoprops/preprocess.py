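"""Instrument-effect removal.

Covers the steps between raw tomogram and estimation-ready A-lines:

* axial confocal PSF correction ``I / H(z - z_f, z_R)`` with the Lorentzian
  ``H = ((z - z_f)/z_R)^2 + 1)^-1`` of a Gaussian beam, and its two-position
  exhaustive-search calibration;
* temporal B-scan averaging for speckle reduction;
* background subtraction;
* noise-floor localisation, log-linear exponential fitting and extrapolation
  to infinite depth, which removes the floor-induced underestimation of the
  depth-resolved attenuation estimate.

Sensitivity roll-off is treated as identity by default (negligible for a
long-coherence swept source) but an arbitrary per-depth correction vector is
accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.ndimage import uniform_filter1d
from scipy.signal import medfilt

from .core import AScanProfile, BScan, ExponentialTail, to_db

__all__ = [
    "PsfModel",
    "CalibrationPair",
    "NoiseFloorFit",
    "PreprocessConfig",
    "NoiseFloorCrossingError",
    "average_bscans",
    "subtract_background",
    "psf_apply",
    "psf_correct",
    "calibrate_psf",
    "fit_noise_floor",
    "extrapolate_tail",
    "attach_tail_from_fit",
]

#: default exhaustive-search grids for the PSF calibration (mm)
DEFAULT_ZR_GRID = np.round(np.arange(0.01, 2.0 + 1e-9, 0.01), 6)
DEFAULT_ZF_GRID = np.round(np.arange(-1.0, 3.0 + 1e-9, 0.01), 6)

#: a trace sitting exactly on the floor level approaches it from above;
#: the crossing is accepted within this margin (dB)
FLOOR_CROSS_MARGIN_DB = 1.0


class NoiseFloorCrossingError(RuntimeError):
    """The dB trace never crosses the configured thresholds; the caller
    should treat the full profile as signal."""


@dataclass(frozen=True)
class PsfModel:
    """Axial confocal point-spread function of a focused Gaussian beam.

    z_R : Rayleigh length (mm), > 0
    z_f : focal depth relative to the depth axis reference (mm)
    """

    z_R: float
    z_f: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_R > 0:
            raise ValueError("z_R must be > 0")

    def h(self, z) -> np.ndarray:
        """Lorentzian sensitivity factor, 1 at focus, 1/2 one Rayleigh
        length away."""
        u = (np.asarray(z, dtype=float) - self.z_f) / self.z_R
        return 1.0 / (u * u + 1.0)


@dataclass(frozen=True)
class CalibrationPair:
    """Two B-scans of the same reflector at depths differing by ``delta_z``
    (mm, image2 deeper)."""

    image1: BScan
    image2: BScan
    delta_z: float

    def __post_init__(self) -> None:
        if self.image1.grid.dz != self.image2.grid.dz:
            raise ValueError("calibration images must share the pixel pitch")
        if not self.delta_z > 0:
            raise ValueError("delta_z must be > 0 (identical depths are degenerate)")


@dataclass(frozen=True)
class NoiseFloorFit:
    """Result of the distal-end exponential fit ``I(z) ~ prefactor *
    exp(-2 mu_tilde z)`` on the window ``(z_nf0, z_nf1)``.

    ``floor_level`` is the additive noise-floor intensity estimated from
    the flat region beyond ``z_nf1`` (0 when that region is too short); it
    is subtracted before fitting so the fitted decay is that of the signal,
    not of signal-plus-floor.
    """

    z_nf0: float
    z_nf1: float
    mu_tilde: float
    prefactor: float
    floor_level: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_nf0 < self.z_nf1:
            raise ValueError("z_nf0 must be < z_nf1")
        if not self.mu_tilde > 0:
            raise ValueError("mu_tilde must be > 0")


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing stage.

    n_average : temporal averaging window in B-scans
    floor_db : dB level defining the noise floor depth z_nf1 (default 50)
    start_db : dB level defining the fit start z_nf0 (default 58)
    db_ref : linear-intensity reference of the dB scale (the floor levels
        are quoted without a reference; keep it overridable)
    subtract_background : subtract a per-depth background trace if given
    """

    n_average: int = 5
    floor_db: float = 50.0
    start_db: float = 58.0
    db_ref: float = 1.0
    subtract_background: bool = True

    def __post_init__(self) -> None:
        if self.n_average < 1:
            raise ValueError("n_average must be >= 1")
        if not self.start_db > self.floor_db:
            raise ValueError("start_db must exceed floor_db")


# ---------------------------------------------------------------------------
# averaging / background / PSF
# ---------------------------------------------------------------------------


def average_bscans(stack: Sequence[BScan], n_average: int | None = None) -> BScan:
    """Elementwise temporal mean over the first ``n_average`` frames.

    For independent fully developed speckle this reduces the intensity
    variance by ~1/n_average.
    """
    if not stack:
        raise ValueError("empty stack")
    n = len(stack) if n_average is None else n_average
    if len(stack) < n:
        raise ValueError(f"need >= {n} B-scans, got {len(stack)}")
    first = stack[0]
    for b in stack[1:n]:
        if b.grid != first.grid or b.values.shape != first.values.shape:
            raise ValueError("B-scan geometry mismatch in averaging stack")
    mean = np.mean([b.values for b in stack[:n]], axis=0)
    return BScan(first.grid, mean, first.lateral_pitch)


def subtract_background(bscan: BScan, background: np.ndarray) -> BScan:
    """Subtract a per-depth background trace (clipping at zero)."""
    bg = np.asarray(background, dtype=float).reshape(-1, 1)
    if bg.shape[0] != bscan.grid.n:
        raise ValueError("background length does not match grid")
    return BScan(bscan.grid, np.clip(bscan.values - bg, 0.0, None), bscan.lateral_pitch)


def psf_apply(bscan: BScan, psf: PsfModel) -> BScan:
    """Multiply by H(z) — degrades an ideal raster the way the instrument
    does (fixture generation and calibration synthesis)."""
    h = psf.h(bscan.grid.depths).reshape(-1, 1)
    return BScan(bscan.grid, bscan.values * h, bscan.lateral_pitch)


def psf_correct(
    bscan: BScan, psf: PsfModel, roll_off: np.ndarray | None = None
) -> BScan:
    """Divide out the axial PSF (and optionally a roll-off vector T(z))."""
    h = psf.h(bscan.grid.depths).reshape(-1, 1)
    values = bscan.values / h
    if roll_off is not None:
        t = np.asarray(roll_off, dtype=float).reshape(-1, 1)
        if t.shape[0] != bscan.grid.n:
            raise ValueError("roll_off length does not match grid")
        values = values / t
    return BScan(bscan.grid, values, bscan.lateral_pitch)


# ---------------------------------------------------------------------------
# PSF calibration
# ---------------------------------------------------------------------------


def calibrate_psf(
    pair: CalibrationPair,
    grid_zR: np.ndarray | None = None,
    grid_zf: np.ndarray | None = None,
) -> PsfModel:
    """Exhaustive-search estimate of (z_R, z_f).

    Minimises the L1 norm, summed over all A-scans of the depth overlap, of
    ``I1(z)/H(z - z_f) - I2(z + dz)/H(z + dz - z_f)`` over the Cartesian
    search grids.  Ties break toward the smallest z_R, then smallest z_f.
    """
    zR_grid = DEFAULT_ZR_GRID if grid_zR is None else np.asarray(grid_zR, dtype=float)
    zf_grid = DEFAULT_ZF_GRID if grid_zf is None else np.asarray(grid_zf, dtype=float)
    if zR_grid.size == 0 or zf_grid.size == 0:
        raise ValueError("empty search grid")

    g1, g2 = pair.image1.grid, pair.image2.grid
    dz = g1.dz
    shift = int(round(pair.delta_z / dz))
    if shift < 1:
        raise ValueError("delta_z is below one pixel — degenerate pair")
    # overlap: sample i of image1 at depth z matches image2 at depth z+delta_z
    z1 = g1.depths
    z2 = g2.depths
    # index in image2 of depth z1[i] + delta_z
    off = int(round((z1[0] + pair.delta_z - z2[0]) / dz))
    lo = max(0, -off)
    hi = min(g1.n, g2.n - off)
    if hi <= lo:
        raise ValueError("empty depth overlap between the calibration images")
    a = pair.image1.values[lo:hi]
    b = pair.image2.values[lo + off : hi + off]
    za = z1[lo:hi]
    zb = za + pair.delta_z

    best = (math.inf, math.inf, math.inf)  # (cost, z_R, z_f)
    for zR in zR_grid:
        # vectorised over the z_f grid: (n_zf, n_depth)
        inv1 = ((za[None, :] - zf_grid[:, None]) / zR) ** 2 + 1.0
        inv2 = ((zb[None, :] - zf_grid[:, None]) / zR) ** 2 + 1.0
        # cost per z_f: sum_z sum_cols |a*inv1 - b*inv2|
        diff = np.abs(
            a[None, :, :] * inv1[:, :, None] - b[None, :, :] * inv2[:, :, None]
        )
        costs = diff.sum(axis=(1, 2))
        j = int(np.argmin(costs))
        cand = (float(costs[j]), float(zR), float(zf_grid[j]))
        if cand[0] < best[0]:
            best = cand
    return PsfModel(z_R=best[1], z_f=best[2])


# ---------------------------------------------------------------------------
# noise floor
# ---------------------------------------------------------------------------


def fit_noise_floor(
    aline: AScanProfile, config: PreprocessConfig = PreprocessConfig()
) -> NoiseFloorFit:
    """Locate the distal fit window on the dB trace and fit the average
    attenuation near the distal end.

    The window start ``z_nf0`` / end ``z_nf1`` are the first depths beyond
    the intensity maximum where the median-filtered dB trace falls to
    ``start_db`` / ``floor_db``.  The fit is log-linear least squares on
    ``ln I`` vs ``z`` (slope ``-2 mu_tilde``); a coupled nonlinear fit of
    ``a * mu * exp(-2 mu z)`` is available with ``coupled=True`` on
    :func:`_fit_window`.
    """
    z = aline.grid.depths
    v = np.clip(aline.values, 0.0, None)
    db = to_db(v, config.db_ref)
    db = np.where(np.isfinite(db), db, -1e12)
    smooth = medfilt(db, kernel_size=5)
    peak = int(np.argmax(smooth))
    after = smooth[peak:]
    idx0 = np.nonzero(after <= config.start_db)[0]
    if idx0.size == 0:
        raise NoiseFloorCrossingError(
            "profile never falls to start_db; treat the full profile as signal"
        )
    i0 = peak + int(idx0[0])
    # a trace sitting exactly on the floor approaches floor_db from above
    # without crossing it; accept arrival within a small margin
    idx1 = np.nonzero(smooth[i0:] <= config.floor_db + FLOOR_CROSS_MARGIN_DB)[0]
    if idx1.size == 0:
        raise NoiseFloorCrossingError(
            "profile never falls to floor_db; treat the full profile as signal"
        )
    i1 = i0 + int(idx1[0])
    if i1 - i0 < 5:
        raise NoiseFloorCrossingError("fit window narrower than 5 samples")
    # estimate the additive floor from the flat region beyond z_nf1 and fit
    # the floor-subtracted signal, otherwise the fitted decay is biased
    # shallow by the floor contribution inside the window
    floor_level = float(np.median(v[i1:])) if v.size - i1 >= 10 else 0.0
    fit_v = np.clip(v[i0:i1] - floor_level, 0.0, None)
    mu_tilde, prefactor = _fit_window(z[i0:i1], fit_v)
    # refine amplitude, decay and floor jointly on everything beyond z_nf0;
    # the initial floor estimate is residual-signal-contaminated, which
    # over-steepens the log-linear fit
    try:
        def model(x, a, m, c):
            return a * np.exp(-2.0 * m * x) + c

        popt, _ = curve_fit(
            model,
            z[i0:],
            v[i0:],
            p0=(prefactor, mu_tilde, floor_level),
            bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        prefactor, mu_tilde, floor_level = (float(p) for p in popt)
    except Exception:
        pass  # keep the log-linear estimates
    return NoiseFloorFit(
        z_nf0=float(z[i0]),
        z_nf1=float(z[i1]),
        mu_tilde=mu_tilde,
        prefactor=prefactor,
        floor_level=floor_level,
    )


def _fit_window(z: np.ndarray, v: np.ndarray, coupled: bool = False):
    mask = v > 0
    if mask.sum() < 5:
        raise NoiseFloorCrossingError("fewer than 5 positive samples in fit window")
    zz, vv = z[mask], v[mask]
    slope, intercept = np.polyfit(zz, np.log(vv), 1)
    mu = -slope / 2.0
    if mu <= 0:
        raise NoiseFloorCrossingError("fit window is not decaying")
    pref = math.exp(intercept)
    if coupled:
        # amplitude-decay coupled model a * mu * exp(-2 mu z)
        def model(x, a, m):
            return a * m * np.exp(-2.0 * m * x)

        popt, _ = curve_fit(model, zz, vv, p0=(pref / mu, mu), maxfev=10000)
        a, m = popt
        mu, pref = float(m), float(a * m)
    return float(mu), float(pref)


def extrapolate_tail(aline: AScanProfile, fit: NoiseFloorFit) -> AScanProfile:
    """Remove the noise floor: subtract the estimated floor level from the
    signal region, replace values deeper than ``z_nf1`` by the fitted
    exponential, and attach the analytic tail so every ``int_z^inf``
    includes the exact remainder ``prefactor/(2 mu) * exp(-2 mu z_end)``."""
    z = aline.grid.depths
    values = np.clip(aline.values - fit.floor_level, 0.0, None)
    beyond = z > fit.z_nf1
    values[beyond] = fit.prefactor * np.exp(-2.0 * fit.mu_tilde * z[beyond])
    tail = ExponentialTail(
        amplitude=fit.prefactor, mu=fit.mu_tilde, z_start=aline.grid.z_end
    )
    return AScanProfile(aline.grid, values, tail=tail)


def attach_tail_from_fit(
    aline: AScanProfile, fit_fraction: float = 0.2
) -> AScanProfile:
    """Attach an analytic tail fitted on the distal part of the signal
    support (for profiles without a detectable noise floor, e.g., simulated
    data whose grid simply ends).

    The fit runs on a lightly smoothed trace (sparse or speckled deep
    signal leaves gaps in the raw one) and the window is widened from
    ``fit_fraction`` of the support toward half of it until the fitted
    decay is positive.
    """
    if aline.tail is not None:
        return aline
    v = np.clip(aline.values, 0.0, None)
    pos = np.nonzero(v > 0)[0]
    if pos.size < 10:
        raise ValueError("too little signal to fit a tail")
    smooth = uniform_filter1d(v, size=9, mode="nearest")
    z = aline.grid.depths
    last_err: Exception | None = None
    for frac in (fit_fraction, 0.35, 0.5):
        start = pos[0] + int((1.0 - frac) * (pos[-1] - pos[0]))
        window = slice(max(start, pos[0]), pos[-1] + 1)
        try:
            mu, pref = _fit_window(z[window], smooth[window])
        except NoiseFloorCrossingError as exc:
            last_err = exc
            continue
        tail = ExponentialTail(amplitude=pref, mu=mu, z_start=aline.grid.z_end)
        return aline.with_tail(tail)
    raise ValueError(f"could not fit a decaying tail: {last_err}")
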