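"""Core containers for infrared spectra and hyperspectral cubes.

Wavenumber grids are stored in descending order (high to low wavenumber,
the acquisition convention); constructors accept either orientation and
canonicalize.  A :class:`SpectralCube` holds one absorbance spectrum per
pixel of a mapped tissue area on a shared grid, together with the zone
(SZ/MZ/DZ), dietary group (C/HMB) and animal labels that the downstream
statistics need.

Cubes round-trip through a plain-text convention: ``cube.csv`` with one
row per pixel (row-major order) and one column per wavenumber, plus a
``cube.json`` sidecar carrying the grid and the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ZONES = ("SZ", "MZ", "DZ")
GROUPS = ("C", "HMB")


def build_grid(hi: float, lo: float, step: float) -> np.ndarray:
    """Descending wavenumber grid from ``hi`` down to (at least) ``lo``.

    The grid starts exactly at ``hi`` with spacing ``step`` and contains
    every point >= ``lo``: ``floor((hi - lo)/step) + 1`` points.  The
    working range 1730-960 cm^-1 sampled at 3.93 cm^-1 yields 196 points.
    """
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    if hi <= lo:
        raise ValueError(f"need hi > lo, got hi={hi}, lo={lo}")
    # small epsilon guards against floating-point shortfall at the last point
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return hi - step * np.arange(n, dtype=float)


def _canonical_descending(w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return a strictly descending copy of ``w`` and whether it was flipped."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavenumber grid must be a 1-D vector of length >= 2")
    d = np.diff(w)
    if np.all(d < 0):
        return w, False
    if np.all(d > 0):
        return w[::-1].copy(), True
    raise ValueError("wavenumber grid must be strictly monotone")


def window_mask(wavenumbers: np.ndarray, hi: float, lo: float) -> np.ndarray:
    """Boolean mask of grid points inside the closed interval [lo, hi].

    Bounds given in either order are auto-swapped.
    """
    if hi < lo:
        hi, lo = lo, hi
    return (wavenumbers >= lo) & (wavenumbers <= hi)


@dataclass
class Spectrum:
    """A single absorbance spectrum on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        w, flipped = _canonical_descending(self.wavenumbers)
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != np.asarray(self.wavenumbers).shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        if flipped:
            a = a[::-1].copy()
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance values must be finite")
        self.wavenumbers = w
        self.absorbance = a

    def __len__(self) -> int:
        return self.wavenumbers.size

    def window(self, hi: float, lo: float) -> "Spectrum":
        m = window_mask(self.wavenumbers, hi, lo)
        if not m.any():
            raise ValueError(f"window [{lo}, {hi}] cm^-1 does not overlap the grid")
        return Spectrum(self.wavenumbers[m], self.absorbance[m])

    def max_in(self, hi: float, lo: float) -> float:
        return float(self.window(hi, lo).absorbance.max())


@dataclass
class SpectralCube:
    """Pixel-indexed absorbance spectra of one mapped tissue section.

    ``data`` has shape (ny, nx, m); pixel (iy, ix) carries the spectrum
    ``data[iy, ix]`` on the shared descending ``grid``.
    """

    grid: np.ndarray
    data: np.ndarray
    pixel_pitch_um: float = 1.1
    zone: str | None = None
    group: str | None = None
    animal_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid, flipped = _canonical_descending(self.grid)
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("cube data must have shape (ny, nx, m)")
        if flipped:
            data = data[..., ::-1].copy()
        if data.shape[-1] != grid.size:
            raise ValueError(
                f"last data axis ({data.shape[-1]}) must match grid length ({grid.size})"
            )
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("cube must contain at least one pixel")
        self.grid = grid
        self.data = data

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.ny * self.nx

    def pixel(self, iy: int, ix: int) -> Spectrum:
        return Spectrum(self.grid, self.data[iy, ix])

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.grid, self.data.reshape(-1, self.grid.size).mean(axis=0))

    def flat(self) -> np.ndarray:
        """Pixels in row-major order, shape (ny*nx, m)."""
        return self.data.reshape(-1, self.grid.size)

    def with_data(self, grid: np.ndarray, data: np.ndarray, **meta_updates) -> "SpectralCube":
        new = replace(self, grid=grid, data=data)
        new.meta = {**self.meta, **meta_updates}
        return new

    # ---------------------------------------------------------------- I/O

    def to_dir(self, path: str | Path, float_fmt: str = "%.9g") -> list[Path]:
        """Write ``cube.csv`` + ``cube.json`` into ``path``; return file list."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        csv_path = path / "cube.csv"
        cols = [f"{w:.4f}" for w in self.grid]
        frame = pd.DataFrame(self.flat(), columns=cols)
        frame.to_csv(csv_path, index=False, float_format=float_fmt)
        sidecar = {
            "wavenumbers": [round(float(w), 6) for w in self.grid],
            "nx": self.nx,
            "ny": self.ny,
            "pixel_pitch_um": self.pixel_pitch_um,
            "zone": self.zone,
            "group": self.group,
            "animal_id": self.animal_id,
            "meta": _jsonable(self.meta),
        }
        json_path = path / "cube.json"
        json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return [csv_path, json_path]

    @classmethod
    def from_dir(cls, path: str | Path) -> "SpectralCube":
        path = Path(path)
        sidecar = json.loads((path / "cube.json").read_text())
        frame = pd.read_csv(path / "cube.csv")
        grid = np.asarray(sidecar["wavenumbers"], dtype=float)
        ny, nx = sidecar["ny"], sidecar["nx"]
        data = frame.to_numpy(dtype=float).reshape(ny, nx, grid.size)
        return cls(
            grid=grid,
            data=data,
            pixel_pitch_um=sidecar.get("pixel_pitch_um", 1.1),
            zone=sidecar.get("zone"),
            group=sidecar.get("group"),
            animal_id=sidecar.get("animal_id"),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
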