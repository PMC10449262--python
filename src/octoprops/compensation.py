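"""Attenuation-compensated intensity reconstruction and display rendering.

The compensated intensity replaces the attenuated irradiance by its
incident value: ``I_D(z) = 2 R(z) mu(z) betaL(0)``, which removes the
accumulated ``exp(-2 int mu)`` loss and is depth-independent for
homogeneous samples.  Rendering maps linear intensity to an 8-bit raster
through a dB stretch with gamma correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AScanProfile, BScan, OpticalProfile, to_db

__all__ = ["DisplayConfig", "compensate", "compensate_maps", "render"]


@dataclass(frozen=True)
class DisplayConfig:
    """Display mapping: gamma exponent (default 0.75, contrast enhancement)
    and the dB dynamic range to stretch over [0, 255]."""

    gamma: float = 0.75
    db_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.db_range is not None and not self.db_range[1] > self.db_range[0]:
            raise ValueError("db_range must be an increasing pair")


def compensate(profile: OpticalProfile, beta_L0: float) -> AScanProfile:
    """Pointwise compensated intensity ``I_D = 2 R mu betaL0`` (zero where
    R is undefined)."""
    if not beta_L0 > 0:
        raise ValueError("beta_L0 must be > 0")
    values = 2.0 * np.nan_to_num(profile.R) * np.nan_to_num(profile.mu) * beta_L0
    return AScanProfile(profile.grid, values)


def compensate_maps(
    mu_map: np.ndarray, R_map: np.ndarray, beta_L0: float
) -> np.ndarray:
    """B-scan variant of :func:`compensate` for solver output maps."""
    if not beta_L0 > 0:
        raise ValueError("beta_L0 must be > 0")
    return 2.0 * np.nan_to_num(R_map) * np.nan_to_num(mu_map) * beta_L0


def render(
    values: np.ndarray | BScan,
    display: DisplayConfig = DisplayConfig(),
    db_ref: float = 1.0,
) -> np.ndarray:
    """Render linear intensity as an 8-bit raster.

    dB-convert, clip to the display range, normalise to [0, 1], apply the
    gamma exponent and scale to [0, 255] integers; monotone in the input.
    """
    data = values.values if isinstance(values, BScan) else np.asarray(values)
    if not np.all(np.isfinite(data)):
        raise ValueError("render requires finite values")
    db = to_db(np.clip(data, 0.0, None), db_ref)
    finite = db[np.isfinite(db)]
    if display.db_range is None:
        if finite.size == 0 or finite.max() == finite.min():
            lo, hi = 0.0, 1.0
        else:
            lo, hi = float(finite.min()), float(finite.max())
    else:
        lo, hi = display.db_range
    if not hi > lo:
        raise ValueError("empty display range")
    db = np.clip(db, lo, hi)
    norm = (db - lo) / (hi - lo)
    return np.round(255.0 * norm**display.gamma).astype(np.uint8)
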