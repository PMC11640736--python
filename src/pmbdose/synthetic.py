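"""Synthetic study inputs: minibeam dose maps, depth-dose curves, calorimeter traces.

Everything downstream (aperture statistics, correction factors, trace
analysis) is exercised on the outputs of this module, which emulates

* a planar proton minibeam field: 15 slits, 400 um wide, 4 mm center-to-center
  pitch, 5 cm slit length, inside a 7.2 x 7.2 cm^2 field, with depth-dependent
  Gaussian beamlet broadening, a uniform valley scatter background, and a
  linear dose non-uniformity along the beamlets;
* pristine and spread-out Bragg depth-dose curves (an analytic surrogate shape,
  used only to exercise the r80 range-scaling procedure);
* graphite-calorimeter signal traces in quasi-adiabatic (core temperature) and
  active isothermal (electrical power) modes, including stepped beam intensity
  emulating SOBP energy-layer switching.

All stochastic outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.special import erf

from .maps import SPACING_600DPI, DoseMap2D

__all__ = [
    "MinibeamFieldSpec",
    "minibeam_dose",
    "generate_minibeam_map",
    "DepthDoseCurve",
    "generate_depth_dose",
    "CalorimeterTrace",
    "generate_calorimeter_trace",
]


# ===========================================================================
# Minibeam lateral dose maps
# ===========================================================================

@dataclass(frozen=True)
class MinibeamFieldSpec:
    """Geometry and beam-model parameters of a planar minibeam field.

    Defaults describe the mono-energetic (100 MeV, 2.0 cm water-equivalent
    depth) configuration.  ``sobp()`` returns the spread-out-Bragg-peak-depth
    variant: more lateral scatter (larger blur, larger valley background).

    blur_sigma is the Gaussian lateral broadening of each beamlet at the
    measurement depth; valley_fraction is a uniform scatter background as a
    fraction of ``peak_dose``; vertical_gradient is the fractional dose change
    per mm along the slit direction (positive = more dose above the field
    center); tilt_asymmetry adds a linear per-slit amplitude ramp across the
    field mimicking a collimator tilt.
    """

    n_slits: int = 15
    slit_width: float = 0.4            # mm
    pitch: float = 4.0                 # mm, center-to-center
    slit_length: float = 50.0          # mm
    field_extent: tuple[float, float] = (72.0, 72.0)  # mm (x, y)
    blur_sigma: float = 0.9            # mm
    valley_fraction: float = 0.05      # [0, 1)
    vertical_gradient: float = 0.0033  # /mm; calibrated so kvert(-11 mm) ~ 0.964
    tilt_asymmetry: float = 0.0        # per-slit amplitude ramp, dimensionless
    peak_dose: float = 10.0            # Gy (overall amplitude scale)
    noise_sd: float = 0.0              # Gy, per-pixel Gaussian noise

    def __post_init__(self) -> None:
        if self.n_slits < 1:
            raise ValueError("invariant violated: n_slits >= 1")
        if not self.slit_width < self.pitch:
            raise ValueError("invariant violated: slit_width < pitch")
        span = (self.n_slits - 1) * self.pitch + self.slit_width
        if span > self.field_extent[0]:
            raise ValueError(
                "invariant violated: (n_slits - 1)*pitch + slit_width "
                f"= {span} mm exceeds horizontal field extent "
                f"{self.field_extent[0]} mm")
        if not self.blur_sigma > 0:
            raise ValueError("invariant violated: blur_sigma > 0")
        if not 0 <= self.valley_fraction < 1:
            raise ValueError("invariant violated: 0 <= valley_fraction < 1")
        if self.noise_sd < 0:
            raise ValueError("invariant violated: noise_sd >= 0")

    @property
    def slit_centers(self) -> np.ndarray:
        """x positions of the slit centers, mm, symmetric about 0."""
        i = np.arange(self.n_slits)
        return (i - (self.n_slits - 1) / 2.0) * self.pitch

    @property
    def slit_amplitudes(self) -> np.ndarray:
        """Per-slit amplitude ramp encoding the collimator-tilt asymmetry."""
        n = self.n_slits
        if n == 1:
            return np.ones(1)
        i = np.arange(n)
        return 1.0 + self.tilt_asymmetry * (2 * i - (n - 1)) / (n - 1)

    def sobp(self, blur_sigma: float = 1.3, valley_fraction: float = 0.10
             ) -> "MinibeamFieldSpec":
        """Variant at SOBP measurement depth (10 cm WED): same slit geometry,
        broader beamlets and stronger valley scatter."""
        return replace(self, blur_sigma=blur_sigma,
                       valley_fraction=valley_fraction)


# smoothing length of the slit-end cosine roll-off, mm
_END_RAMP = 2.0


def _end_envelope(y: np.ndarray, slit_length: float) -> np.ndarray:
    """1 inside the slit band, raised-cosine roll-off over the last 2 mm."""
    half = slit_length / 2.0
    a = np.abs(y)
    env = np.zeros_like(a)
    env[a <= half - _END_RAMP] = 1.0
    ramp = (a > half - _END_RAMP) & (a <= half)
    env[ramp] = 0.5 * (1.0 + np.cos(np.pi * (a[ramp] - (half - _END_RAMP))
                                    / _END_RAMP))
    return env


def minibeam_dose(spec: MinibeamFieldSpec, x: np.ndarray, y: np.ndarray
                  ) -> np.ndarray:
    """Noise-free generating function of the minibeam field, evaluated at
    physical coordinates (broadcast over ``x`` and ``y``), in Gy.

    dose = peak_dose * [v + (1 - v) * sum_i ramp_i * G_i(x)]
                     * (1 + g*y) * E(y) * inside_field(x, y)

    with G_i a slit top-hat of width ``slit_width`` convolved with a Gaussian
    of ``blur_sigma`` (an erf difference), E(y) the cosine-smoothed slit-length
    envelope and the whole expression zero outside the field extent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s2 = np.sqrt(2.0) * spec.blur_sigma
    hw = spec.slit_width / 2.0
    profile = np.zeros_like(x)  # depends on x only; broadcasts against y below
    for ci, ai in zip(spec.slit_centers, spec.slit_amplitudes):
        profile += ai * 0.5 * (erf((x - ci + hw) / s2) - erf((x - ci - hw) / s2))
    v = spec.valley_fraction
    lateral = v + (1.0 - v) * profile
    vertical = np.clip(1.0 + spec.vertical_gradient * y, 0.0, None)
    dose = spec.peak_dose * lateral * vertical * _end_envelope(y, spec.slit_length)
    inside = ((np.abs(x) <= spec.field_extent[0] / 2.0)
              & (np.abs(y) <= spec.field_extent[1] / 2.0))
    return np.where(inside, dose, 0.0)


def generate_minibeam_map(spec: MinibeamFieldSpec, seed: int | None = None,
                          pixel_spacing: float = SPACING_600DPI,
                          pad_mm: float = 0.0) -> DoseMap2D:
    """Rasterize the minibeam field onto a cell-centered grid.

    The grid covers the field extent (optionally plus ``pad_mm`` of zero-dose
    margin on every side, so large detector footprints near the field edge can
    still be integrated).  Per-pixel Gaussian noise of sd ``spec.noise_sd`` is
    added and the result clipped at zero; a seed is mandatory whenever the
    output is stochastic.  Identical spec + seed gives bit-identical maps.
    """
    if spec.noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    ex = spec.field_extent[0] + 2.0 * pad_mm
    ey = spec.field_extent[1] + 2.0 * pad_mm
    nx = int(np.ceil(ex / pixel_spacing - 1e-9))
    ny = int(np.ceil(ey / pixel_spacing - 1e-9))
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing
    values = minibeam_dose(spec, x[None, :], y[:, None])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)
    return DoseMap2D(values, pixel_spacing, (0.0, 0.0),
                     meta={"generator": "minibeam", "seed": seed})


# ===========================================================================
# Depth-dose curves
# ===========================================================================

@dataclass
class DepthDoseCurve:
    """A sampled depth-dose curve in a single medium (arbitrary dose scale)."""

    depths: np.ndarray           # mm, strictly increasing
    dose: np.ndarray             # Gy or arbitrary units, >= 0
    medium: Literal["water", "graphite"] = "water"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.dose.shape:
            raise ValueError("depths and dose must be matching 1D arrays")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    def normalized(self) -> "DepthDoseCurve":
        """Percentage-depth-dose form: dose scaled to its own maximum (=1)."""
        return DepthDoseCurve(self.depths.copy(), self.dose / self.dose.max(),
                              self.medium)


def _pristine_shape(z: np.ndarray, z_peak: float, sigma: float) -> np.ndarray:
    """Analytic Bragg-like surrogate: slowly rising power-law buildup plus a
    Gaussian-broadened peak; the distal edge decays with the peak Gaussian."""
    z = np.asarray(z, dtype=float)
    zp = np.minimum(z, z_peak)
    buildup = 0.28 * (1.0 + 0.8 * (zp / z_peak) ** 1.8)
    distal = np.where(z > z_peak,
                      np.exp(-0.5 * ((z - z_peak) / (0.8 * sigma)) ** 2), 1.0)
    peak = np.exp(-0.5 * ((z - z_peak) / sigma) ** 2)
    return buildup * distal + peak


def _distal_crossing(depths: np.ndarray, dose: np.ndarray,
                     level: float) -> float:
    """First depth beyond the maximum where dose crosses ``level`` (linear
    interpolation between bracketing samples)."""
    imax = int(np.argmax(dose))
    below = np.nonzero(dose[imax:] < level)[0]
    if below.size == 0:
        raise ValueError("curve truncated before r80")
    i = imax + below[0]
    z0, z1 = depths[i - 1], depths[i]
    d0, d1 = dose[i - 1], dose[i]
    return float(z0 + (level - d0) * (z1 - z0) / (d1 - d0))


def generate_depth_dose(range_mm: float,
                        medium: Literal["water", "graphite"] = "water",
                        sobp_width_mm: float = 0.0,
                        step_mm: float = 0.1) -> DepthDoseCurve:
    """Generate a pristine or spread-out Bragg depth-dose curve.

    A pristine curve has its distal 80% falloff (r80) at ``range_mm`` exactly
    (up to the depth grid): the surrogate shape is rescaled in depth after its
    r80 is located numerically.  A SOBP (``sobp_width_mm > 0``) is a
    non-negative-least-squares weighted sum of shifted pristine components
    whose peaks span ``[range_mm - sobp_width_mm, range_mm]``, flattening the
    plateau over that interval to within 1%.
    """
    if not range_mm > 0:
        raise ValueError("range_mm must be > 0")
    if sobp_width_mm < 0:
        raise ValueError("sobp_width_mm must be >= 0")
    if sobp_width_mm >= range_mm:
        raise ValueError("sobp_width_mm must be smaller than range_mm")

    sigma = max(0.35, 0.012 * range_mm)

    if sobp_width_mm == 0.0:
        z_peak = range_mm - 0.668 * sigma
        z = np.arange(0.0, range_mm + 4.0 * sigma + step_mm, step_mm)
        dose = _pristine_shape(z, z_peak, sigma)
        r80 = _distal_crossing(z, dose, 0.8 * dose.max())
        z = z * (range_mm / r80)   # pin r80 to the requested range
        # resample back onto a uniform grid of the requested step
        zu = np.arange(0.0, z[-1], step_mm)
        dose = np.interp(zu, z, dose)
        return DepthDoseCurve(zu, dose, medium)

    # SOBP: component peaks spanning the modulation interval (the deepest
    # layer overshoots the plateau end by 0.45 sigma so the distal plateau
    # edge can be held up).  Weights come from non-negative least squares,
    # with Lawson-style reweighting toward the minimax (equal-ripple)
    # solution, which keeps the plateau flat to well within 1%.
    lo = range_mm - sobp_width_mm
    hi = range_mm + 0.45 * sigma
    n_comp = max(12, int(np.ceil((hi - lo) / (0.3 * sigma))) + 1)
    peaks = np.linspace(lo, hi, n_comp)
    z = np.arange(0.0, range_mm + 4.0 * sigma + step_mm, step_mm)
    comps = np.stack([_pristine_shape(z, zp, sigma) for zp in peaks], axis=1)
    plateau = (z >= lo) & (z <= range_mm)
    a = comps[plateau]
    lawson = np.full(a.shape[0], 1.0 / a.shape[0])
    best = None
    for _ in range(40):
        sw = np.sqrt(lawson)
        weights, _ = nnls(a * sw[:, None], sw)
        resid = a @ weights - 1.0
        flat = resid.max() - resid.min()
        if best is None or flat < best[0]:
            best = (flat, weights)
        lawson *= np.abs(resid) + 1e-12
        lawson /= lawson.sum()
    dose = comps @ best[1]
    return DepthDoseCurve(z, dose, medium)


# ===========================================================================
# Calorimeter traces
# ===========================================================================

@dataclass
class CalorimeterTrace:
    """Uniformly sampled calorimeter signal with its irradiation window.

    ``signal`` is the core temperature relative to baseline in mK
    (quasi-adiabatic mode) or the electrical heating power in mW (active
    isothermal mode).
    """

    time: np.ndarray                    # s
    signal: np.ndarray                  # mK or mW
    mode: Literal["quasi_adiabatic", "isothermal"] = "quasi_adiabatic"
    irradiation: tuple[float, float] = (0.0, 0.0)     # [t_start, t_end], s
    layer_steps: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be matching 1D arrays")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("sampling interval must be constant")
        t0, t1 = self.irradiation
        if not t0 < t1:
            raise ValueError("irradiation window requires t_start < t_end")
        if t0 < self.time[0] or t1 > self.time[-1]:
            raise ValueError("irradiation window must lie inside the trace")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def _intensity_knots(irradiation: tuple[float, float],
                     layer_steps: Sequence[tuple[float, float]] | None,
                     dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Segment boundaries and piecewise-constant beam intensities over the
    irradiation window, with times snapped to the sample grid."""
    t0, t1 = (round(t / dt) * dt for t in irradiation)
    bounds = [t0]
    intens = []
    if layer_steps:
        steps = sorted((round(t / dt) * dt, i) for t, i in layer_steps)
        if any(not t0 <= t < t1 for t, _ in steps):
            raise ValueError("layer step times must lie within the "
                             "irradiation window")
        if steps[0][0] > t0:
            intens.append(1.0)
            bounds.append(steps[0][0])
        for k, (t, i) in enumerate(steps):
            if i < 0:
                raise ValueError("layer intensities must be non-negative")
            intens.append(i)
            nxt = steps[k + 1][0] if k + 1 < len(steps) else t1
            bounds.append(nxt)
    else:
        intens.append(1.0)
        bounds.append(t1)
    return np.asarray(bounds), np.asarray(intens)


def generate_calorimeter_trace(
        mode: Literal["quasi_adiabatic", "isothermal"],
        true_dose: float,
        *,
        c: float = 706.0,              # specific heat of the graphite core, J/(kg K)
        mass: float = 7.2e-4,          # core mass, kg (16 mm dia x 2 mm disc)
        baseline_power: float = 10.0,  # mW, isothermal mode only
        drift_rate: float = 0.0,       # mK/s (QA) or mW/s (isothermal)
        noise_sd: float = 0.0,         # mK or mW
        irradiation: tuple[float, float] = (120.0, 180.0),
        layer_steps: Sequence[tuple[float, float]] | None = None,
        seed: int | None = None,
        duration: float = 300.0,
        dt: float = 0.1) -> CalorimeterTrace:
    """Synthesize a calorimeter trace that encodes a known delivered dose.

    Quasi-adiabatic: a linear baseline drift plus a temperature ramp during
    irradiation totalling dT = true_dose / c, shaped in time by the
    (optionally stepped) beam intensity.  Isothermal: ``baseline_power`` plus
    drift, minus a power depression whose time integral equals
    ``true_dose * mass``.  Window and layer-step times are snapped to the
    sample grid and discontinuous signals take the mean of their one-sided
    limits at the jump sample, so the trapezoidal analysis round-trips the
    dose exactly in the noise-free case.
    """
    if not c > 0 or not mass > 0:
        raise ValueError("c and mass must be > 0")
    if true_dose < 0:
        raise ValueError("true_dose must be >= 0")
    t0, t1 = irradiation
    if not t0 < t1:
        raise ValueError("irradiation requires t_start < t_end")
    if t0 < 0 or t1 > duration:
        raise ValueError("irradiation window must lie inside the trace")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")

    t = np.arange(0.0, duration + dt / 2.0, dt)
    bounds, intens = _intensity_knots((t0, t1), layer_steps, dt)
    t0s, t1s = bounds[0], bounds[-1]
    seg_len = np.diff(bounds)
    total = float((intens * seg_len).sum())
    if true_dose > 0 and total <= 0:
        raise ValueError("total beam intensity over the window must be > 0")

    if mode == "quasi_adiabatic":
        # cumulative energy fraction: piecewise linear with kinks on the grid
        cum = np.concatenate(([0.0], np.cumsum(intens * seg_len)))
        frac = (np.interp(t, bounds, cum / total if total > 0 else cum)
                if total > 0 else np.zeros_like(t))
        frac[t < t0s] = 0.0
        frac[t > t1s] = 1.0 if total > 0 else 0.0
        dT_mK = 1000.0 * true_dose / c
        signal = drift_rate * t + dT_mK * frac
    elif mode == "isothermal":
        # power depression in mW; 1 J = 1000 mW*s
        scale = 1000.0 * true_dose * mass / total if total > 0 else 0.0

        def _i_at(times: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(bounds, times, side="right") - 1
            out = np.zeros_like(times)
            ok = (idx >= 0) & (idx < len(intens)) & (times < t1s) & (times >= t0s)
            out[ok] = intens[idx[ok]]
            return out

        # midpoint convention at grid-aligned discontinuities
        depression = scale * 0.5 * (_i_at(t - dt / 4.0) + _i_at(t + dt / 4.0))
        signal = baseline_power + drift_rate * t - depression
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    return CalorimeterTrace(
        t, signal, mode, (float(t0s), float(t1s)),
        list(layer_steps or []),
        meta={"true_dose_Gy": true_dose, "c": c, "mass_kg": mass,
              "baseline_power_mW": baseline_power, "seed": seed})
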