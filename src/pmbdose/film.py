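"""Radiochromic-film processing: scan averaging, net optical density,
calibration fitting and application.

The workflow mirrors standard EBT3 practice: each film piece is scanned
several times and the scans averaged per pixel to suppress scanner noise;
the darkening signal is the net optical density
netOD = log10(I_unexposed / I_irradiated) of a single (red-channel-
equivalent) scanner channel; dose is obtained from a monotone calibration
curve dose = a*netOD + b*netOD**n fitted to films irradiated at a known dose
scale.  No correction is applied for LET quenching of the film response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .maps import DoseMap2D

__all__ = ["ScanStack", "average_scans", "net_optical_density",
           "CalibrationCurve", "CalibrationError", "fit_calibration",
           "apply_calibration"]


class CalibrationError(ValueError):
    """Raised when a calibration fit is unusable (e.g. non-monotone)."""


@dataclass
class ScanStack:
    """Repeated scanner images of one film piece (identical shape), plus the
    scan resolution in dpi."""

    images: list[np.ndarray]
    dpi: float = 600.0

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("a scan stack needs at least one image")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        shape = self.images[0].shape
        for k, im in enumerate(self.images):
            if im.shape != shape:
                raise ValueError(f"image {k} has shape {im.shape}, "
                                 f"expected {shape}")
        if not self.dpi > 0:
            raise ValueError("dpi must be > 0")

    @property
    def pixel_spacing(self) -> float:
        return 25.4 / self.dpi


def average_scans(stack: ScanStack) -> np.ndarray:
    """Per-pixel arithmetic mean of the repeated scans (noise reduction:
    pixel variance falls as 1/k for k independent scans)."""
    return np.mean(stack.images, axis=0)


def net_optical_density(irradiated: np.ndarray,
                        unexposed: np.ndarray) -> np.ndarray:
    """netOD = log10(unexposed / irradiated), per pixel.  Both rasters must
    be strictly positive (scanner transmission values)."""
    irradiated = np.asarray(irradiated, dtype=float)
    unexposed = np.asarray(unexposed, dtype=float)
    for name, arr in (("irradiated", irradiated), ("unexposed", unexposed)):
        if np.any(arr <= 0):
            raise ValueError(f"{name} raster contains non-positive pixels")
    return np.log10(unexposed / irradiated)


@dataclass
class CalibrationCurve:
    """Monotone dose-vs-netOD calibration, dose = a*netOD + b*netOD**n.

    The form passes through the origin (zero netOD -> zero dose) and, with
    non-negative coefficients and n in [1, 3], is monotone over the validity
    range, which spans the calibration points.
    """

    a: float
    b: float
    n: float
    netod_range: tuple[float, float]
    dose_range: tuple[float, float]
    residual_sd: float = 0.0          # Gy
    form: str = "dose = a*netOD + b*netOD**n"
    meta: dict = field(default_factory=dict)

    def dose(self, netod):
        """Evaluate the curve; values above the validity range are clipped
        to its upper end with a warning, negative netOD clips to zero."""
        netod = np.asarray(netod, dtype=float)
        hi = self.netod_range[1]
        n_over = int((netod > hi).sum())
        if n_over:
            warnings.warn(f"{n_over} netOD values above the calibration "
                          f"range were clipped to {hi:.4g}", stacklevel=2)
        x = np.clip(netod, 0.0, hi)
        return self.a * x + self.b * x ** self.n

    def netod(self, dose_gy: float) -> float:
        """Inverse of the curve (scalar), by bracketed root finding."""
        lo, hi = 0.0, self.netod_range[1] * 1.5 + 1e-9
        return float(brentq(lambda x: self.a * x + self.b * x ** self.n
                            - dose_gy, lo, hi))

    def is_monotone(self, n_grid: int = 512) -> bool:
        x = np.linspace(self.netod_range[0], self.netod_range[1], n_grid)
        d = self.a * x + self.b * x ** self.n
        return bool(np.all(np.diff(d) >= -1e-12 * max(1.0, d[-1])))


def fit_calibration(netod_points, dose_points) -> CalibrationCurve:
    """Least-squares fit of dose = a*netOD + b*netOD**n (n free in [1, 3]).

    Requires at least 4 points including 0 Gy, non-negative doses, and a
    monotone relation between netOD and dose; a non-monotone input (e.g.
    duplicate netOD at different doses) or a non-monotone fitted curve raises
    :class:`CalibrationError`.
    """
    x = np.asarray(netod_points, dtype=float)
    d = np.asarray(dose_points, dtype=float)
    if x.shape != d.shape or x.ndim != 1:
        raise ValueError("netOD and dose points must be matching 1D arrays")
    if len(x) < 4:
        raise ValueError("at least 4 calibration points are required")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if not np.any(d == 0):
        raise ValueError("the calibration scale must include 0 Gy")
    order = np.argsort(x, kind="stable")
    x, d = x[order], d[order]
    if np.any((np.diff(x) < 1e-12) & (np.abs(np.diff(d)) > 1e-12)):
        raise CalibrationError("duplicate netOD values at different doses; "
                               "dose-vs-netOD is not monotone")
    if np.any(np.diff(d) < -1e-12):
        raise CalibrationError("dose is not monotone in netOD")

    def model(xx, a, b, n):
        return a * xx + b * np.power(np.clip(xx, 0.0, None), n)

    a0 = max((d[-1] - d[0]) / max(x[-1] - x[0], 1e-9), 1.0)
    popt, _ = curve_fit(model, x, d, p0=(a0, 1.0, 2.0),
                        bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 3.0]),
                        maxfev=20000)
    a, b, n = (float(v) for v in popt)
    resid = d - model(x, a, b, n)
    dof = max(len(x) - 3, 1)
    curve = CalibrationCurve(a, b, n,
                             (float(x.min()), float(x.max())),
                             (float(d.min()), float(d.max())),
                             residual_sd=float(np.sqrt((resid ** 2).sum()
                                                       / dof)))
    if not curve.is_monotone():
        raise CalibrationError("fitted calibration curve is not monotone "
                               "over its validity range")
    return curve


def apply_calibration(netod_map: np.ndarray, curve: CalibrationCurve,
                      dpi: float = 600.0,
                      origin: tuple[float, float] = (0.0, 0.0)) -> DoseMap2D:
    """Convert a netOD raster to a dose map; the pixel spacing is 25.4/dpi
    mm (0.04233 mm at 600 dpi)."""
    dose = curve.dose(netod_map)
    return DoseMap2D(np.clip(dose, 0.0, None), 25.4 / dpi, origin,
                     meta={"calibration": curve.form, "dpi": dpi})
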