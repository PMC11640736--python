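"""Dose-to-water assembly and the uncertainty budget.

Dw = Dcore_m * (Dw_MC/Dg_MC) * kimp * kgap [* kvert], a pure product, so
fractional (percent) uncertainties combine exactly in quadrature with no
linearization error.  Conventions: components are standard uncertainties
(k = 1) in fractional percent; the expanded uncertainty is k = 2; a maximum
deviation quoted as an expanded (k = 2) uncertainty is halved before entering
the quadrature.

Which kvert applies depends on the configuration: in the mono-energetic
set-up the calorimeter itself measures at (0, -11) mm so its dose needs no
vertical correction (kvert corrects the chamber measurements made at the
field center); in the SOBP set-up the calorimeter measures at the field
center and kvert(PSPC) is part of its own dose equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .factors import CorrectionFactor
from .positioning import quadrature

__all__ = ["UncertaintyBudget", "DoseResult", "dose_to_water",
           "expanded_to_standard", "RatioReport", "ratio_report",
           "REQUIRED_FACTORS"]

REQUIRED_FACTORS = {
    "mono": ("dose_conversion", "kimp", "kgap"),
    "sobp": ("dose_conversion", "kimp", "kgap", "kvert_pspc"),
}


@dataclass
class UncertaintyBudget:
    """Fractional-percent uncertainty components and their combination.

    Each component is (name, type_a %, type_b %), k = 1.  The combined value
    is recomputable from the components at any time (bit-exact round trip
    through serialization).
    """

    components: list[tuple[str, float, float]] = field(default_factory=list)

    def add(self, name: str, type_a: float = 0.0, type_b: float = 0.0) -> None:
        if type_a < 0 or type_b < 0:
            raise ValueError("uncertainty components must be >= 0")
        self.components.append((name, float(type_a), float(type_b)))

    def combined(self) -> float:
        """Combined standard uncertainty (k = 1), %: quadrature over every
        Type A and Type B entry."""
        flat = [u for _, a, b in self.components for u in (a, b)]
        return quadrature(flat) if flat else 0.0

    def expanded(self, k: float = 2.0) -> float:
        return k * self.combined()

    def to_dict(self) -> dict:
        return {"components": [list(c) for c in self.components]}

    @classmethod
    def from_dict(cls, d: dict) -> "UncertaintyBudget":
        return cls([(str(n), float(a), float(b))
                    for n, a, b in d["components"]])


def expanded_to_standard(max_deviation: float) -> float:
    """Convert a maximum deviation treated as an expanded uncertainty (k = 2)
    to a standard uncertainty (k = 1): divide by 2."""
    if max_deviation < 0:
        raise ValueError("deviation must be >= 0")
    return max_deviation / 2.0


@dataclass
class DoseResult:
    """Dose-to-water with its uncertainty budget."""

    dw: float                       # Gy
    combined_percent: float         # k = 1
    expanded_percent: float         # k = 2
    budget: UncertaintyBudget
    config: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.dw > 0:
            raise ValueError("Dw must be > 0")
        if abs(self.combined_percent - self.budget.combined()) > 1e-12:
            raise ValueError("combined uncertainty inconsistent with budget")
        if abs(self.expanded_percent - 2.0 * self.combined_percent) > 1e-12:
            raise ValueError("expanded must be 2 x combined")

    def to_dict(self) -> dict:
        return {"dw_Gy": self.dw, "combined_percent": self.combined_percent,
                "expanded_percent": self.expanded_percent,
                "config": self.config, "label": self.label,
                **self.budget.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "DoseResult":
        return cls(d["dw_Gy"], d["combined_percent"], d["expanded_percent"],
                   UncertaintyBudget.from_dict(d), d.get("config", ""),
                   d.get("label", ""))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "DoseResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def dose_to_water(d_core: float, factors: list[CorrectionFactor],
                  config: str = "mono",
                  d_core_type_a: float = 0.0,
                  d_core_type_b: float = 0.0,
                  label: str = "") -> DoseResult:
    """Assemble dose-to-water from the measured core dose and the correction
    factors required for ``config`` ("mono" or "sobp").

    Exactly one factor of each required name must be supplied (duplicates,
    extras and omissions are rejected by name).  Dw is the product of
    ``d_core`` and all factor values; the combined uncertainty is the
    quadrature of every factor's Type A and Type B plus the core-dose
    measurement uncertainty components.
    """
    if not d_core > 0:
        raise ValueError("d_core must be > 0")
    if config not in REQUIRED_FACTORS:
        raise ValueError(f"unknown configuration {config!r}; expected one of "
                         f"{sorted(REQUIRED_FACTORS)}")
    required = REQUIRED_FACTORS[config]
    names = [f.name for f in factors]
    dup = sorted({n for n in names if names.count(n) > 1})
    missing = sorted(set(required) - set(names))
    extra = sorted(set(names) - set(required))
    problems = []
    if dup:
        problems.append(f"duplicate factors: {dup}")
    if missing:
        problems.append(f"missing factors: {missing}")
    if extra:
        problems.append(f"unexpected factors for {config!r}: {extra}")
    if problems:
        raise ValueError("; ".join(problems))

    dw = d_core * float(np.prod([f.value for f in factors]))
    budget = UncertaintyBudget()
    budget.add("d_core", d_core_type_a, d_core_type_b)
    for f in sorted(factors, key=lambda f: required.index(f.name)):
        budget.add(f.name, f.type_a, f.type_b)
    combined = budget.combined()
    return DoseResult(dw, combined, 2.0 * combined, budget, config, label)


@dataclass(frozen=True)
class RatioReport:
    """Calorimeter-vs-chamber dose ratio with its uncertainty."""

    ratio: float
    combined_percent: float        # k = 1
    expanded_percent: float        # k = 2
    label: str = ""

    def consistent_with_unity(self, k: float = 2.0) -> bool:
        return abs(self.ratio - 1.0) * 100.0 <= k * self.combined_percent


def ratio_report(calorimeter: DoseResult, chamber: DoseResult,
                 kprof: CorrectionFactor, label: str = "") -> RatioReport:
    """Dose-to-water measured by the calorimeter relative to the chamber,
    with kprof applied to the chamber dose to harmonize the differing
    footprint sizes; uncertainties of both results and of kprof combine in
    quadrature."""
    ratio = calorimeter.dw / (chamber.dw * kprof.value)
    u = quadrature([calorimeter.combined_percent, chamber.combined_percent,
                    kprof.type_a, kprof.type_b])
    return RatioReport(float(ratio), u, 2.0 * u, label)
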