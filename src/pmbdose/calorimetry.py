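"""Graphite-calorimeter trace analysis.

Quasi-adiabatic mode: straight lines are fitted to the pre- and
post-irradiation drift windows of the core temperature and extrapolated to
the irradiation midpoint; the radiation-induced temperature rise is their
difference there, and dose = c * dT.  Extrapolating both drifts to the same
instant cancels any common linear drift exactly.

Active isothermal mode: a single baseline line is fitted across the pre and
post windows of the electrical heating power; the dose is the time integral
of the radiation-induced power depression (baseline minus measured power)
divided by the core mass.

Signals follow the trace convention of :mod:`pmbdose.synthetic`: mK for
temperature, mW for power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import CalorimeterTrace

__all__ = ["CalorimeterConstants", "DriftFit", "fit_drift",
           "analyze_quasi_adiabatic", "analyze_isothermal",
           "ModeCombination", "combine_modes"]


@dataclass(frozen=True)
class CalorimeterConstants:
    """Specific heat capacity (J/(kg K)) and mass (kg) of the core."""

    specific_heat: float = 706.0
    core_mass: float = 7.2e-4

    def __post_init__(self) -> None:
        if not self.specific_heat > 0 or not self.core_mass > 0:
            raise ValueError("specific heat and core mass must be > 0")


@dataclass(frozen=True)
class DriftFit:
    """Least-squares line over a drift window of a trace."""

    window: tuple[float, float]
    slope: float           # signal units per s
    intercept: float       # signal units at t = 0
    residual_sd: float

    def __call__(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def fit_drift(trace: CalorimeterTrace, window: tuple[float, float],
              min_samples: int = 10) -> DriftFit:
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window requires t1 > t0")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError("window must lie inside the trace")
    sel = (trace.time >= t0) & (trace.time <= t1)
    if sel.sum() < min_samples:
        raise ValueError(f"drift window holds {int(sel.sum())} samples; "
                         f"at least {min_samples} required")
    t = trace.time[sel]
    s = trace.signal[sel]
    slope, intercept = np.polyfit(t, s, 1)
    resid = s - (intercept + slope * t)
    return DriftFit((t0, t1), float(slope), float(intercept),
                    float(resid.std(ddof=2)) if len(t) > 2 else 0.0)


def _check_windows(trace: CalorimeterTrace,
                   pre_window: tuple[float, float],
                   post_window: tuple[float, float]) -> None:
    t0, t1 = trace.irradiation
    if pre_window[1] >= t0:
        raise ValueError("pre-irradiation window must end strictly before "
                         "the irradiation starts")
    if post_window[0] <= t1:
        raise ValueError("post-irradiation window must start strictly after "
                         "the irradiation ends")


def analyze_quasi_adiabatic(trace: CalorimeterTrace,
                            consts: CalorimeterConstants | None = None,
                            pre_window: tuple[float, float] | None = None,
                            post_window: tuple[float, float] | None = None,
                            residual_threshold: float = 0.05) -> float:
    """Dose to the core (Gy) from a quasi-adiabatic temperature trace.

    dT is the difference, at the irradiation midpoint, between the post- and
    pre-irradiation drift lines; dose = c * dT (with dT converted from mK to
    K).  A fit residual sd above ``residual_threshold`` (mK) triggers a
    warning; a temperature drop clearly beyond the fit noise is rejected.
    """
    if trace.mode != "quasi_adiabatic":
        raise ValueError("trace is not in quasi-adiabatic mode")
    if consts is None:
        consts = CalorimeterConstants()
    t0, t1 = trace.irradiation
    if pre_window is None:
        pre_window = (max(trace.time[0], t0 - 60.0), t0 - trace.dt)
    if post_window is None:
        post_window = (t1 + trace.dt, min(trace.time[-1], t1 + 60.0))
    _check_windows(trace, pre_window, post_window)
    pre = fit_drift(trace, pre_window)
    post = fit_drift(trace, post_window)
    for f in (pre, post):
        if f.residual_sd > residual_threshold:
            warnings.warn(f"drift fit over {f.window} has residual sd "
                          f"{f.residual_sd:.4g} mK above threshold",
                          stacklevel=2)
    t_mid = 0.5 * (t0 + t1)
    dT_mK = float(post(t_mid) - pre(t_mid))
    noise = 3.0 * max(pre.residual_sd, post.residual_sd)
    if dT_mK < -noise:
        raise ValueError(f"negative temperature rise ({dT_mK:.4g} mK) "
                         "beyond fit noise; heating sign convention violated")
    return consts.specific_heat * dT_mK / 1000.0


def analyze_isothermal(trace: CalorimeterTrace,
                       consts: CalorimeterConstants | None = None,
                       pre_window: tuple[float, float] | None = None,
                       post_window: tuple[float, float] | None = None,
                       residual_threshold: float = 0.05) -> float:
    """Dose to the core (Gy) from an active-isothermal power trace.

    The baseline electrical power is a single line fitted jointly over the
    pre and post windows; the radiation-induced depression (baseline minus
    measured power, mW) is integrated by the trapezoidal rule over the whole
    interval between the two drift windows — the depression vanishes outside
    the irradiation, and integrating across it keeps the trapezoidal sum
    exact for stepped (energy-layer) depressions — and divided by the core
    mass (1 mW s = 1e-3 J).
    """
    if trace.mode != "isothermal":
        raise ValueError("trace is not in isothermal mode")
    if consts is None:
        consts = CalorimeterConstants()
    t0, t1 = trace.irradiation
    if pre_window is None:
        pre_window = (max(trace.time[0], t0 - 60.0), t0 - trace.dt)
    if post_window is None:
        post_window = (t1 + trace.dt, min(trace.time[-1], t1 + 60.0))
    _check_windows(trace, pre_window, post_window)
    sel = (((trace.time >= pre_window[0]) & (trace.time <= pre_window[1]))
           | ((trace.time >= post_window[0]) & (trace.time <= post_window[1])))
    if sel.sum() < 20:
        raise ValueError("too few samples in the drift windows")
    slope, intercept = np.polyfit(trace.time[sel], trace.signal[sel], 1)
    resid = trace.signal[sel] - (intercept + slope * trace.time[sel])
    residual_sd = float(resid.std(ddof=2))
    if residual_sd > residual_threshold:
        warnings.warn(f"baseline fit residual sd {residual_sd:.4g} mW above "
                      "threshold", stacklevel=2)
    # two extra samples either side keep the trapezoidal sum exact for
    # depressions that switch on/off exactly at the window edges
    margin = 2.0 * trace.dt
    span = (trace.time >= t0 - margin) & (trace.time <= t1 + margin)
    t = trace.time[span]
    depression = (intercept + slope * t) - trace.signal[span]   # mW
    energy_mWs = float(np.trapezoid(depression, t))
    return energy_mWs * 1e-3 / consts.core_mass


@dataclass(frozen=True)
class ModeCombination:
    """Mean of the two operating modes with a consistency metric."""

    dose: float               # Gy, arithmetic mean
    half_difference: float    # Gy, |qa - iso| / 2
    relative_disagreement: float
    inconsistent: bool        # True if the modes disagree by > 1%


def combine_modes(dose_qa: float, dose_iso: float,
                  tolerance: float = 0.01) -> ModeCombination:
    """Mean of the quasi-adiabatic and isothermal doses; their half-difference
    is reported as a consistency metric and flagged (with a warning) when the
    relative disagreement exceeds ``tolerance``."""
    if not dose_qa > 0 or not dose_iso > 0:
        raise ValueError("both mode doses must be > 0")
    mean = 0.5 * (dose_qa + dose_iso)
    half_diff = 0.5 * abs(dose_qa - dose_iso)
    rel = abs(dose_qa - dose_iso) / mean
    flag = rel > tolerance
    if flag:
        warnings.warn(f"quasi-adiabatic and isothermal doses disagree by "
                      f"{100 * rel:.2f}%", stacklevel=2)
    return ModeCombination(mean, half_diff, rel, flag)
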