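"""Correction factors of the dose-to-water equation.

Dose-to-water is assembled as

    Dw = Dcore_m * (Dw_MC / Dg_MC) * kimp * kgap * kvert

where Dcore_m is the measured dose to the graphite core and the remaining
factors correct, in turn, for the graphite-to-water dose conversion, the
non-graphite constituents of the calorimeter (kimp), the vacuum gaps around
the core (kgap), and the vertical measurement position in a field that is
non-uniform along the beamlets (kvert).  kprof additionally harmonizes the
differing footprint sizes of the calorimeter core (8.0 mm radius) and the
Roos chamber (7.8 mm radius).

Film-derived factors (kvert, kprof) are ratios of DAP per unit area between
two apertures on repeated film dose maps; Monte-Carlo-derived factors
(kimp, kgap) are ratios of externally scored core doses between geometry
configurations; the dose conversion factor comes from r80 range scaling of
water and graphite percentage-depth-dose curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .dap import (PSPC_RADIUS, ROOS_RADIUS, SensitiveRegion, dap_per_area)
from .maps import DoseMap2D
from .positioning import PositioningModel, TypeBResult, quadrature
from .synthetic import DepthDoseCurve

__all__ = [
    "CorrectionFactor", "ScoredDoseSet",
    "compute_kvert", "compute_kprof", "compute_kimp", "compute_kgap",
    "find_r80", "compute_dose_conversion",
    "positional_type_b_on_factor", "percent_deviation_from_unity",
]


@dataclass
class CorrectionFactor:
    """A named multiplicative correction with standard uncertainties.

    ``type_a`` and ``type_b`` are fractional percent at k = 1.
    """

    name: str
    value: float
    type_a: float = 0.0
    type_b: float = 0.0
    note: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("factor value must be > 0")
        if self.type_a < 0 or self.type_b < 0:
            raise ValueError("uncertainties must be >= 0")

    def combined(self) -> float:
        """Combined standard uncertainty (quadrature of Type A and B), %."""
        return quadrature([self.type_a, self.type_b])

    def to_dict(self) -> dict:
        return {"name": self.name, "value": self.value,
                "type_a_percent": self.type_a, "type_b_percent": self.type_b,
                "note": self.note}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionFactor":
        return cls(d["name"], d["value"], d["type_a_percent"],
                   d["type_b_percent"], d.get("note", ""))


@dataclass(frozen=True)
class ScoredDoseSet:
    """Core doses scored externally in the three calorimeter-model geometries:
    full (impurities + gaps), pure graphite (gaps only), and compensated
    (homogeneous graphite).  Uncertainties are statistical, fractional %."""

    d_full: float
    d_pure: float
    d_compensated: float
    u_full: float = 0.0
    u_pure: float = 0.0
    u_compensated: float = 0.0

    def __post_init__(self) -> None:
        if min(self.d_full, self.d_pure, self.d_compensated) <= 0:
            raise ValueError("scored doses must be > 0")
        if min(self.u_full, self.u_pure, self.u_compensated) < 0:
            raise ValueError("uncertainties must be >= 0")


def percent_deviation_from_unity(value: float) -> float:
    """|1 - value| as a percentage — e.g. the center-vs-offset dose
    difference implied by a kvert value."""
    return abs(1.0 - value) * 100.0


# ===========================================================================
# Film-derived factors
# ===========================================================================

def _ratio_factor(maps: list[DoseMap2D], name: str,
                  regions_num_den) -> CorrectionFactor:
    if len(maps) < 2:
        raise ValueError("at least 2 repeated film maps are required")
    ratios = []
    for m in maps:
        num_region, den_region = regions_num_den
        num = dap_per_area(m, num_region)
        den = dap_per_area(m, den_region)
        ratios.append(num / den)
    ratios = np.asarray(ratios)
    value = float(ratios.mean())
    type_a = float(ratios.std(ddof=1) / value) * 100.0
    return CorrectionFactor(name, value, type_a=type_a,
                            note=f"mean of {len(maps)} film maps; Type A = "
                                 "sd of the per-film ratios")


def compute_kvert(maps: list[DoseMap2D], radius: float,
                  target: tuple[float, float] = (0.0, -11.0),
                  reference: tuple[float, float] = (0.0, 0.0),
                  name: str = "kvert") -> CorrectionFactor:
    """Vertical-position correction: mean over repeated film maps of
    DAP-per-area(target) / DAP-per-area(reference) for one aperture radius;
    the standard deviation of the per-film ratios is the Type A uncertainty."""
    return _ratio_factor(maps, name,
                         (SensitiveRegion(target, radius),
                          SensitiveRegion(reference, radius)))


def compute_kprof(maps: list[DoseMap2D],
                  center: tuple[float, float] = (0.0, -11.0),
                  radius_num: float = PSPC_RADIUS,
                  radius_den: float = ROOS_RADIUS) -> CorrectionFactor:
    """Footprint-size correction: mean over repeated film maps of the ratio
    of DAP per unit area between the calorimeter-core aperture (8.0 mm) and
    the Roos aperture (7.8 mm) at the same center."""
    return _ratio_factor(maps, "kprof",
                         (SensitiveRegion(center, radius_num),
                          SensitiveRegion(center, radius_den)))


# ===========================================================================
# Monte-Carlo-ratio factors
# ===========================================================================

def compute_kimp(s: ScoredDoseSet) -> CorrectionFactor:
    """Impurity correction: scored dose in the pure-graphite geometry over
    the full geometry; statistical uncertainties combine in quadrature."""
    return CorrectionFactor("kimp", s.d_pure / s.d_full,
                            type_a=quadrature([s.u_pure, s.u_full]),
                            note="ratio of scored core doses, "
                                 "pure-graphite / full geometry")


def compute_kgap(s: ScoredDoseSet) -> CorrectionFactor:
    """Vacuum-gap correction: scored dose in the compensated (homogeneous)
    geometry over the pure-graphite geometry."""
    return CorrectionFactor("kgap", s.d_compensated / s.d_pure,
                            type_a=quadrature([s.u_compensated, s.u_pure]),
                            note="ratio of scored core doses, "
                                 "compensated / pure-graphite geometry")


# ===========================================================================
# Dose conversion via r80 range scaling
# ===========================================================================

def find_r80(curve: DepthDoseCurve) -> float:
    """Distal depth at which the dose first falls to 80% of its maximum,
    by linear interpolation between the bracketing samples."""
    dmax = curve.dose.max()
    if dmax <= 0:
        raise ValueError("curve has no positive dose")
    imax = int(np.argmax(curve.dose))
    below = np.nonzero(curve.dose[imax:] < 0.8 * dmax)[0]
    if below.size == 0:
        raise ValueError("curve truncated before r80")
    i = imax + below[0]
    z0, z1 = curve.depths[i - 1], curve.depths[i]
    d0, d1 = curve.dose[i - 1], curve.dose[i]
    return float(z0 + (0.8 * dmax - d0) * (z1 - z0) / (d1 - d0))


def compute_dose_conversion(pdd_water: DepthDoseCurve,
                            pdd_graphite: DepthDoseCurve,
                            ref_depth: float) -> CorrectionFactor:
    """Graphite-to-water dose conversion factor by range scaling.

    Both curves are first normalized to their own maximum (percentage depth
    dose); the graphite depth axis is then scaled so its r80 matches that of
    water, and the factor is the ratio water/graphite of the interpolated
    doses at ``ref_depth`` (mm, water-equivalent).
    """
    w = pdd_water.normalized()
    g = pdd_graphite.normalized()
    scale = find_r80(w) / find_r80(g)
    g_depths = g.depths * scale
    for depths, label in ((w.depths, "water"), (g_depths, "scaled graphite")):
        if not depths[0] <= ref_depth <= depths[-1]:
            raise ValueError(f"ref_depth {ref_depth} mm outside the "
                             f"{label} curve")
    dw = float(PchipInterpolator(w.depths, w.dose)(ref_depth))
    dg = float(PchipInterpolator(g_depths, g.dose)(ref_depth))
    return CorrectionFactor("dose_conversion", dw / dg,
                            note=f"r80 scaling factor {scale:.6f}, "
                                 f"ratio at {ref_depth} mm WED")


# ===========================================================================
# Positional Type B on film-derived factors
# ===========================================================================

def _raw_dap_curve(maps: list[DoseMap2D], center: tuple[float, float],
                   radius: float, axis: str,
                   offsets: np.ndarray) -> PchipInterpolator:
    """Unnormalized DAP per unit area versus a displacement of ``center``
    along one axis, averaged over the film maps."""
    vals = np.zeros_like(offsets)
    for m in maps:
        for k, o in enumerate(offsets):
            cx = center[0] + (o if axis == "horizontal" else 0.0)
            cy = center[1] + (o if axis == "vertical" else 0.0)
            vals[k] += dap_per_area(m, SensitiveRegion((cx, cy), radius))
    vals /= len(maps)
    return PchipInterpolator(offsets, vals)


def positional_type_b_on_factor(
        maps: list[DoseMap2D],
        factor: str,
        model: PositioningModel | None = None,
        n_samples: int = 1_000_000,
        seed: int | None = None,
        *,
        radius: float = PSPC_RADIUS,
        target: tuple[float, float] = (0.0, -11.0),
        reference: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, -11.0),
        radii: tuple[float, float] = (PSPC_RADIUS, ROOS_RADIUS),
        scan_halfwidth: float = 2.0,
        scan_step: float = 0.5) -> TypeBResult:
    """Propagate Gaussian positioning errors through a film-derived factor.

    For ``factor="kvert"`` the two apertures entering the ratio are the same
    radius at ``target`` and ``reference``; for ``factor="kprof"`` they are the
    two ``radii`` at the common ``center``.  Per axis, a common positional
    offset is drawn for both apertures (the detector assembly moves as one),
    the unnormalized DAP trends are evaluated at the displaced positions, the
    factor ratio is recomputed per sample, and the standard deviation of the
    sampled ratios (as %) is the per-axis Type B; axes combine in quadrature.
    """
    if model is None:
        model = PositioningModel()
    if not maps:
        raise ValueError("at least one map is required")
    if n_samples < 1000:
        import warnings
        warnings.warn("n_samples < 1000 gives an unstable Type B estimate",
                      stacklevel=2)
    offsets = np.arange(-scan_halfwidth, scan_halfwidth + 1e-9, scan_step)
    if model.sigma * 2.0 > scan_halfwidth:
        raise ValueError("scan_halfwidth must cover 2 sigma")

    if factor == "kvert":
        pairs = [((target, radius), (reference, radius))]
    elif factor == "kprof":
        pairs = [((center, radii[0]), (center, radii[1]))]
    else:
        raise ValueError("factor must be 'kvert' or 'kprof'")
    (num_c, num_r), (den_c, den_r) = pairs[0]

    rng = np.random.default_rng(seed)
    per_axis = []
    for axis in ("horizontal", "vertical"):
        f_num = _raw_dap_curve(maps, num_c, num_r, axis, offsets)
        f_den = _raw_dap_curve(maps, den_c, den_r, axis, offsets)
        draws = rng.normal(0.0, model.sigma, n_samples)
        np.clip(draws, offsets[0], offsets[-1], out=draws)
        ratios = f_num(draws) / f_den(draws)
        per_axis.append(float(ratios.std(ddof=1) / ratios.mean()) * 100.0)
    u_h, u_v = per_axis
    return TypeBResult(u_h, u_v, float(np.hypot(u_h, u_v)), n_samples, seed)
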