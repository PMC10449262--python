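"""Shared domain containers and raster I/O for depth-resolved OCT analysis.

Conventions used throughout the package:

* depths are in millimetres and increase into the sample; sample ``i`` of a
  grid sits at ``z0 + i * dz`` (0-based);
* depth windows are half-open index ranges ``[i, j)``;
* intensities are linear-scale A.U. ("square of magnitude"); decibel values
  are ``10 * log10(I / db_ref)`` with a configurable reference (default 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DepthGrid",
    "ExponentialTail",
    "AScanProfile",
    "BScan",
    "OpticalProfile",
    "SystemParams",
    "LayerSpec",
    "to_db",
    "from_db",
    "read_bscan",
    "write_bscan",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when raster data and its grid metadata disagree."""


# ---------------------------------------------------------------------------
# depth grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthGrid:
    """Uniform depth axis.

    Parameters
    ----------
    z0 : float
        Depth of the first sample relative to the detector reference (mm).
    dz : float
        Axial pixel pitch (mm), strictly positive.
    n : int
        Number of samples, at least 2.
    """

    z0: float
    dz: float
    n: int

    def __post_init__(self) -> None:
        if not self.dz > 0:
            raise ValueError(f"dz must be > 0, got {self.dz}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def depths(self) -> np.ndarray:
        """Depth of every sample (mm)."""
        return self.z0 + self.dz * np.arange(self.n)

    @property
    def z_end(self) -> float:
        """Depth of the last sample (mm)."""
        return self.z0 + self.dz * (self.n - 1)

    def index_of(self, z: float) -> int:
        """Nearest sample index for depth ``z`` (clipped to the grid)."""
        i = int(round((z - self.z0) / self.dz))
        return min(max(i, 0), self.n - 1)

    def window(self, z1: float, z2: float) -> slice:
        """Half-open index window ``[i, j)`` covering depths in ``[z1, z2)``."""
        if not z2 > z1:
            raise ValueError("window requires z1 < z2")
        i = max(int(math.ceil((z1 - self.z0) / self.dz - 1e-9)), 0)
        j = min(int(math.ceil((z2 - self.z0) / self.dz - 1e-9)), self.n)
        return slice(i, j)

    def to_dict(self) -> dict:
        return {"z0": self.z0, "dz": self.dz, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "DepthGrid":
        return cls(z0=float(d["z0"]), dz=float(d["dz"]), n=int(d["n"]))


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialTail:
    """Analytic single-exponential continuation of an A-scan beyond the grid.

    Represents ``I(z) = amplitude * exp(-2 * mu * z)`` for ``z >= z_start``,
    so semi-infinite depth integrals can include the exact remainder
    ``amplitude / (2 mu) * exp(-2 mu z)``.  ``r`` optionally records the
    backscattering fraction assumed constant over the tail (known for
    simulated fixtures, the deepest segment's value otherwise).
    """

    amplitude: float
    mu: float
    z_start: float
    r: float | None = None

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.amplitude >= 0):
            raise ValueError("tail requires mu > 0 and amplitude >= 0")

    def value(self, z) -> np.ndarray:
        return self.amplitude * np.exp(-2.0 * self.mu * np.asarray(z, dtype=float))

    def integral(self, z_from: float | None = None) -> float:
        """``int_{z_from}^inf I(u) du`` (defaults to the tail start)."""
        z = self.z_start if z_from is None else max(z_from, self.z_start)
        return self.amplitude * math.exp(-2.0 * self.mu * z) / (2.0 * self.mu)


@dataclass(frozen=True)
class AScanProfile:
    """A single depth profile of linear-scale OCT intensity.

    ``tail`` carries the analytic continuation beyond the last sample when
    the profile has been tail-extrapolated (or was simulated in closed form).
    """

    grid: DepthGrid
    values: np.ndarray
    tail: ExponentialTail | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n,):
            raise ValueError(
                f"values length {values.shape} does not match grid n={self.grid.n}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("A-scan values must be finite")

    def clipped(self) -> "AScanProfile":
        """Clip negative (raw, pre-background-subtraction) values to zero."""
        return replace(self, values=np.clip(self.values, 0.0, None))

    def with_tail(self, tail: ExponentialTail | None) -> "AScanProfile":
        return replace(self, tail=tail)


@dataclass(frozen=True)
class BScan:
    """Lateral collection of A-scans sharing a single depth grid.

    ``values`` has shape ``(grid.n, n_alines)`` — depth along rows, lateral
    position along columns, matching the raster layout on disk.
    """

    grid: DepthGrid
    values: np.ndarray
    lateral_pitch: float = 0.01

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != self.grid.n:
            raise ValueError(
                f"B-scan shape {values.shape} does not match grid n={self.grid.n}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("B-scan values must be finite")
        if not self.lateral_pitch > 0:
            raise ValueError("lateral_pitch must be > 0")
        object.__setattr__(self, "values", values)

    @property
    def n_alines(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> AScanProfile:
        return AScanProfile(self.grid, self.values[:, j].copy())

    def columns(self) -> Iterator[AScanProfile]:
        for j in range(self.n_alines):
            yield self.column(j)

    @classmethod
    def from_columns(
        cls, columns: Sequence[AScanProfile], lateral_pitch: float = 0.01
    ) -> "BScan":
        if not columns:
            raise ValueError("need at least one column")
        grid = columns[0].grid
        if any(c.grid != grid for c in columns):
            raise ValueError("all columns must share one grid")
        return cls(grid, np.stack([c.values for c in columns], axis=1), lateral_pitch)


@dataclass(frozen=True)
class OpticalProfile:
    """Per-depth attenuation coefficient mu(z) (1/mm) and backscattering
    fraction R(z) (unitless) on a shared grid.

    NaN marks depths where a quantity is undefined (e.g., above the sample
    surface); where defined, ``mu >= 0`` and ``0 < R < 1``.
    """

    grid: DepthGrid
    mu: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        R = np.asarray(self.R, dtype=float)
        for name, arr in (("mu", mu), ("R", R)):
            if arr.shape != (self.grid.n,):
                raise ValueError(f"{name} length does not match grid")
        if np.any(mu[np.isfinite(mu)] < 0):
            raise ValueError("mu must be >= 0 where defined")
        rf = R[np.isfinite(R)]
        if np.any((rf <= 0) | (rf >= 1)):
            raise ValueError("R must lie in (0, 1) where defined")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "R", R)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"z_mm": self.grid.depths, "mu_per_mm": self.mu, "R": self.R}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OpticalProfile":
        df = pd.read_csv(path)
        z = df["z_mm"].to_numpy()
        dz = float(np.median(np.diff(z)))
        grid = DepthGrid(z0=float(z[0]), dz=dz, n=len(z))
        return cls(grid, df["mu_per_mm"].to_numpy(), df["R"].to_numpy())


@dataclass(frozen=True)
class SystemParams:
    """Instrument constants.

    beta_L0 : digitized incident irradiance beta*L(0) (A.U.*mm)
    na : numerical aperture of the sample arm
    l_coh : coherence length of the source (mm)
    db_ref : linear-intensity reference of the decibel scale (A.U.)
    psf : optional axial PSF model (``preprocess.PsfModel``)
    """

    beta_L0: float
    na: float = 0.05
    l_coh: float = 12.0
    db_ref: float = 1.0
    psf: object | None = None

    def __post_init__(self) -> None:
        if not self.beta_L0 > 0:
            raise ValueError("beta_L0 must be > 0")
        if not (0 < self.na < 1):
            raise ValueError("na must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = {
            "beta_L0": self.beta_L0,
            "na": self.na,
            "l_coh": self.l_coh,
            "db_ref": self.db_ref,
        }
        if self.psf is not None:
            d["psf"] = {"z_R": self.psf.z_R, "z_f": self.psf.z_f}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemParams":
        psf = None
        if d.get("psf") is not None:
            from .preprocess import PsfModel

            psf = PsfModel(z_R=float(d["psf"]["z_R"]), z_f=float(d["psf"]["z_f"]))
        return cls(
            beta_L0=float(d["beta_L0"]),
            na=float(d.get("na", 0.05)),
            l_coh=float(d.get("l_coh", 12.0)),
            db_ref=float(d.get("db_ref", 1.0)),
            psf=psf,
        )


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous layer: thickness (mm, ``inf`` allowed only for the
    final layer of a phantom), attenuation ``mu`` (1/mm) and backscattering
    fraction ``R``."""

    thickness: float
    mu: float
    R: float

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("thickness must be > 0 (inf allowed for last layer)")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0 < self.R < 1):
            raise ValueError("R must lie in (0, 1)")


# ---------------------------------------------------------------------------
# decibel conversion
# ---------------------------------------------------------------------------


def to_db(values, db_ref: float = 1.0) -> np.ndarray:
    """Convert linear intensity to decibels, ``10 log10(I / db_ref)``.

    Zero maps to ``-inf``; negative input is a domain error (clip raw data
    first).
    """
    if not db_ref > 0:
        raise ValueError("db_ref must be > 0")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("to_db requires non-negative intensities")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(v / db_ref)


def from_db(db_values, db_ref: float = 1.0) -> np.ndarray:
    """Inverse of :func:`to_db`."""
    if not db_ref > 0:
        raise ValueError("db_ref must be > 0")
    return db_ref * np.power(10.0, np.asarray(db_values, dtype=float) / 10.0)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"tiff", "text"}:
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return "tiff"
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return "text"
    raise FormatError(f"cannot infer raster format from suffix {path.suffix!r}")


def write_bscan(bscan: BScan, path: str | Path, fmt: str | None = None) -> None:
    """Write a B-scan raster (depth = rows, lateral = columns).

    TIFF stores single-precision pixels with the grid in the image
    description tag; delimited text gets a JSON sidecar ``<path>.json``.
    """
    path = Path(path)
    meta = {"grid": bscan.grid.to_dict(), "lateral_pitch": bscan.lateral_pitch}
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        tifffile.imwrite(
            path, bscan.values.astype(np.float32), description=json.dumps(meta)
        )
    else:
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        np.savetxt(path, bscan.values.astype(np.float32), delimiter=delim)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_bscan(path: str | Path, fmt: str | None = None) -> BScan:
    """Read a B-scan written by :func:`write_bscan`.

    Raises :class:`FormatError` on shape mismatch between raster and grid
    metadata, and ``ValueError`` on non-finite pixels.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is None:
                raise FormatError("TIFF lacks grid metadata in its description tag")
            meta = json.loads(desc.value)
    else:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"missing grid sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        data = np.loadtxt(path, delimiter=delim)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    grid = DepthGrid.from_dict(meta["grid"])
    if data.shape[0] != grid.n:
        raise FormatError(
            f"raster has {data.shape[0]} rows but metadata grid n={grid.n}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("raster contains non-finite pixels")
    return BScan(grid, data, lateral_pitch=float(meta.get("lateral_pitch", 0.01)))
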