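"""Type B dose uncertainty from detector positioning.

The detector is assumed to be placed within +/-1 mm of its nominal position
with 95% confidence, i.e. Gaussian per-axis positioning errors with
sigma = 0.5 mm.  Sampling the normalized DAP-per-unit-area offset-response
curves under that Gaussian and taking the standard deviation of the sampled
values gives the per-axis Type B standard uncertainty (k = 1); the two axes
are treated as independent and combined in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dap import OffsetScan

__all__ = ["PositioningModel", "TypeBResult", "sample_type_b", "quadrature"]


@dataclass(frozen=True)
class PositioningModel:
    """Gaussian detector-positioning model.

    ``confidence_halfwidth`` is the stated 95% half-width in mm; consistency
    with ``sigma`` follows the 2-sigma convention (+/-1 mm at 95% for
    sigma = 0.5 mm).
    """

    mean: tuple[float, float] = (0.0, -11.0)   # nominal (x, y), mm
    sigma: float = 0.5                         # per-axis, mm
    confidence_halfwidth: float = 1.0          # 95% half-width, mm

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if abs(2.0 * self.sigma - self.confidence_halfwidth) > 1e-9:
            raise ValueError("inconsistent model: 2*sigma must equal the "
                             "95% confidence half-width")


@dataclass(frozen=True)
class TypeBResult:
    """Per-axis and combined positioning Type B standard uncertainties,
    as fractional percent (k = 1)."""

    horizontal: float
    vertical: float
    combined: float
    n_samples: int
    seed: int | None = None
    n_clipped: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        expect = float(np.hypot(self.horizontal, self.vertical))
        if abs(self.combined - expect) > 1e-12 * max(1.0, expect):
            raise ValueError("combined must be the quadrature of the "
                             "per-axis values")


def quadrature(components) -> float:
    """Combine standard-uncertainty components in quadrature
    (square root of the sum of squares)."""
    c = np.asarray(components, dtype=float)
    if np.any(c < 0):
        raise ValueError("uncertainty components must be non-negative")
    return float(np.sqrt((c ** 2).sum()))


def _axis_std(scan: OffsetScan, mean: float, sigma: float,
              n_samples: int, rng: np.random.Generator
              ) -> tuple[float, int]:
    lo, hi = scan.span
    if mean - 2.0 * sigma < lo or mean + 2.0 * sigma > hi:
        raise ValueError(
            f"{scan.axis} scan [{lo}, {hi}] mm does not cover "
            f"mean +/- 2 sigma around {mean} mm")
    draws = rng.normal(mean, sigma, n_samples)
    n_clipped = int(((draws < lo) | (draws > hi)).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} of {n_samples} {scan.axis} samples fell "
                      "outside the scan range and were clipped to its ends",
                      stacklevel=3)
    np.clip(draws, lo, hi, out=draws)
    vals = scan.interpolator()(draws)
    return float(vals.std(ddof=1)) * 100.0, n_clipped


def sample_type_b(scan_h: OffsetScan, scan_v: OffsetScan,
                  model: PositioningModel | None = None,
                  n_samples: int = 1_000_000,
                  seed: int | None = None) -> TypeBResult:
    """Monte Carlo propagation of Gaussian positioning errors through the
    normalized offset-response curves.

    Per axis, offsets are drawn from N(mean_axis, sigma), the monotone-cubic
    interpolant of the normalized scan is evaluated at each draw (draws beyond
    the scan range are clipped to its ends and counted), and the standard
    deviation of the sampled values (as %) is the per-axis Type B; the two are
    combined in quadrature.  Deterministic for a fixed seed.
    """
    if model is None:
        model = PositioningModel()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples < 1000:
        warnings.warn("n_samples < 1000 gives an unstable Type B estimate",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    u_h, clip_h = _axis_std(scan_h, model.mean[0], model.sigma, n_samples, rng)
    u_v, clip_v = _axis_std(scan_v, model.mean[1], model.sigma, n_samples, rng)
    return TypeBResult(u_h, u_v, float(np.hypot(u_h, u_v)),
                       n_samples, seed, (clip_h, clip_v))
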