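"""Raster dose maps on a regular, cell-centered grid.

The package-wide coordinate convention: physical coordinates in mm, x across
the minibeam slits, y along them, y increasing upward, origin at the field
center.  Positions below the beam axis (e.g. the calorimeter core at
(0, -11) mm) therefore have negative y.  Internally ``values[i, j]`` holds the
dose of the cell whose center is at ``(x_coords[j], y_coords[i])`` with both
coordinate arrays ascending; image formats that put the first row at the top
are flipped on read/write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DoseMap2D", "write_dose_map_tiff", "read_dose_map_tiff",
           "write_dose_map_csv", "read_dose_map_csv"]

#: pixel spacing of a 600 dpi flatbed scan, mm
SPACING_600DPI = 25.4 / 600.0


@dataclass
class DoseMap2D:
    """Absorbed dose on a regular 2D grid.

    Parameters
    ----------
    values
        Dose in Gy, shape ``(ny, nx)``, row index increasing with y.
    pixel_spacing
        Grid pitch in mm (square pixels).
    origin
        Physical (x, y) position, in mm, of the grid center.
    """

    values: np.ndarray
    pixel_spacing: float = SPACING_600DPI
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_coords(self) -> np.ndarray:
        nx = self.values.shape[1]
        return self.origin[0] + (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_spacing

    @property
    def y_coords(self) -> np.ndarray:
        ny = self.values.shape[0]
        return self.origin[1] + (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_spacing

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """Physical outer edges ``(xmin, xmax, ymin, ymax)`` in mm."""
        h = self.pixel_spacing / 2.0
        x = self.x_coords
        y = self.y_coords
        return (x[0] - h, x[-1] + h, y[0] - h, y[-1] + h)

    def translated(self, dx: float, dy: float) -> "DoseMap2D":
        """Same raster, origin shifted by (dx, dy) mm."""
        return DoseMap2D(self.values.copy(), self.pixel_spacing,
                         (self.origin[0] + dx, self.origin[1] + dy),
                         dict(self.meta))

    def integral(self) -> float:
        """Dose-area product over the whole map, Gy*mm^2."""
        return float(self.values.sum()) * self.pixel_spacing ** 2


# -- serialization ----------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, dose_map: DoseMap2D) -> None:
    meta = {
        "pixel_spacing_mm": dose_map.pixel_spacing,
        "origin_mm": list(dose_map.origin),
    }
    meta.update(dose_map.meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> tuple[float, tuple[float, float], dict]:
    meta = json.loads(_sidecar_path(path).read_text())
    spacing = float(meta.pop("pixel_spacing_mm"))
    origin = tuple(meta.pop("origin_mm"))
    return spacing, origin, meta


def write_dose_map_tiff(path: str | Path, dose_map: DoseMap2D) -> None:
    """Write a single-channel float32 TIFF plus a JSON sidecar with geometry."""
    import tifffile

    path = Path(path)
    # image row 0 is the top of the field -> flip the ascending-y raster
    tifffile.imwrite(path, dose_map.values[::-1].astype(np.float32))
    _write_sidecar(path, dose_map)


def read_dose_map_tiff(path: str | Path) -> DoseMap2D:
    import tifffile

    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)[::-1]
    spacing, origin, meta = _read_sidecar(path)
    return DoseMap2D(values, spacing, origin, meta)


def write_dose_map_csv(path: str | Path, dose_map: DoseMap2D) -> None:
    path = Path(path)
    np.savetxt(path, dose_map.values[::-1], delimiter=",", fmt="%.9g")
    _write_sidecar(path, dose_map)


def read_dose_map_csv(path: str | Path) -> DoseMap2D:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)[::-1]
    spacing, origin, meta = _read_sidecar(path)
    return DoseMap2D(values, spacing, origin, meta)
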