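"""Plain-text interchange formats.

Dose maps travel as float32 TIFF or CSV grids with a JSON sidecar carrying
the pixel spacing and origin (see :mod:`pmbdose.maps`); depth-dose curves and
calorimeter traces as two-column CSV (plus a sidecar for the trace mode,
irradiation window and constants); offset scans as (offset_mm,
normalized_dap) CSV; correction factors as JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dap import OffsetScan
from .factors import CorrectionFactor
from .maps import (read_dose_map_csv, read_dose_map_tiff,  # noqa: F401
                   write_dose_map_csv, write_dose_map_tiff)
from .synthetic import CalorimeterTrace, DepthDoseCurve

__all__ = [
    "write_dose_map_tiff", "read_dose_map_tiff",
    "write_dose_map_csv", "read_dose_map_csv",
    "write_depth_dose", "read_depth_dose",
    "write_trace", "read_trace",
    "write_offset_scan", "read_offset_scan",
    "write_factors", "read_factors",
]


def write_depth_dose(path: str | Path, curve: DepthDoseCurve) -> None:
    header = f"depth_mm,dose  # medium={curve.medium}"
    np.savetxt(path, np.column_stack([curve.depths, curve.dose]),
               delimiter=",", header=header, fmt="%.9g")


def read_depth_dose(path: str | Path, medium: str | None = None
                    ) -> DepthDoseCurve:
    path = Path(path)
    if medium is None:
        first = path.read_text().splitlines()[0]
        medium = first.split("medium=")[1].strip() if "medium=" in first \
            else "water"
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return DepthDoseCurve(data[:, 0], data[:, 1], medium)


def write_trace(path: str | Path, trace: CalorimeterTrace) -> None:
    path = Path(path)
    unit = "mK" if trace.mode == "quasi_adiabatic" else "mW"
    np.savetxt(path, np.column_stack([trace.time, trace.signal]),
               delimiter=",", header=f"time_s,signal_{unit}", fmt="%.9g")
    sidecar = {"mode": trace.mode,
               "irradiation_s": list(trace.irradiation),
               "layer_steps": [list(s) for s in trace.layer_steps]}
    sidecar.update(trace.meta)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> CalorimeterTrace:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mode = meta.pop("mode")
    irradiation = tuple(meta.pop("irradiation_s"))
    steps = [tuple(s) for s in meta.pop("layer_steps", [])]
    return CalorimeterTrace(data[:, 0], data[:, 1], mode, irradiation,
                            steps, meta)


def write_offset_scan(path: str | Path, scan: OffsetScan) -> None:
    header = (f"offset_mm,normalized_dap,raw_dap_Gy  # axis={scan.axis} "
              f"fixed={scan.fixed} radius={scan.radius} "
              f"reference={scan.reference}")
    np.savetxt(path, np.column_stack([scan.offsets, scan.values, scan.raw]),
               delimiter=",", header=header, fmt="%.12g")


def read_offset_scan(path: str | Path) -> OffsetScan:
    path = Path(path)
    first = path.read_text().splitlines()[0]
    fields = dict(tok.split("=") for tok in first.rsplit("#", 1)[1].split())
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return OffsetScan(fields["axis"], float(fields["fixed"]), data[:, 0],
                      data[:, 1], float(fields["reference"]),
                      float(fields["radius"]), data[:, 2])


def write_factors(path: str | Path,
                  factors: list[CorrectionFactor]) -> None:
    Path(path).write_text(json.dumps([f.to_dict() for f in factors],
                                     indent=1))


def read_factors(path: str | Path) -> list[CorrectionFactor]:
    return [CorrectionFactor.from_dict(d)
            for d in json.loads(Path(path).read_text())]
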