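"""Coronary blood flow, flow reserve, and report writing.

Coronary blood flow combines the Doppler-derived stroke distance (VTI) and
heart rate with the color-mode vessel diameter:

    CBF [mL/min] = (pi/4) * D^2 * VTI * HR / 1000

with D in mm, VTI in mm and HR in beats/min (mm^3/min = uL/min, hence the
/1000).  Coronary flow velocity reserve (CFVR) is the ratio of the average
hyperemic to average baseline peak velocity; coronary flow reserve (CFR)
is the same ratio on CBF.  Reduced reserve flags microvascular disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colormode_diameter import DiameterSummary
from .cycle_filter import Rejection, SummaryTable
from .cycle_metrics import CycleLandmarks, CycleMetrics
from .ecg_segmentation import CardiacCycle, PeakSet
from .envelope_extraction import ValidationError
from .strip_io import DopplerStrip

#: Landmark drawing colors (RGB), the field's reporting convention:
#: green = diastolic onset, yellow = peak, pink = decay point,
#: red = peak deceleration, blue = end of cycle.
LANDMARK_COLORS = {
    "diastolic_onset": (0, 200, 0),
    "peak": (255, 215, 0),
    "decay_point": (255, 105, 180),
    "peak_decel": (220, 20, 20),
    "end": (40, 90, 255),
}


def compute_cbf(diameter_mm: float, vti_mm: float, hr_bpm: float) -> float:
    """CBF in mL/min from diameter (mm), VTI (mm) and heart rate (BPM)."""
    for name, v in (("diameter_mm", diameter_mm), ("vti_mm", vti_mm),
                    ("hr_bpm", hr_bpm)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    return math.pi / 4 * diameter_mm ** 2 * vti_mm * hr_bpm / 1000.0


@dataclass
class FlowResult:
    """CBF for one condition with the inputs that produced it."""

    condition: str                  # "baseline" or "hyperemia"
    diameter_mm: float
    vti_mm: float
    hr_bpm: float
    cbf_ml_per_min: float = field(init=False)

    def __post_init__(self) -> None:
        self.cbf_ml_per_min = compute_cbf(self.diameter_mm, self.vti_mm,
                                          self.hr_bpm)


@dataclass
class ReserveResult:
    """Hyperemia-to-baseline ratios: velocity reserve and flow reserve."""

    cfvr: float
    cfr: float


def compute_reserve(baseline_summary: SummaryTable, baseline_flow: FlowResult,
                    hyper_summary: SummaryTable, hyper_flow: FlowResult,
                    ) -> ReserveResult:
    """CFVR from mean peak velocities, CFR from the CBF ratio."""
    pv_base = float(baseline_summary.table.loc["peak_velocity", "mean"])
    pv_hyper = float(hyper_summary.table.loc["peak_velocity", "mean"])
    if not pv_base > 0:
        raise ValidationError("baseline mean peak velocity must be > 0")
    if not baseline_flow.cbf_ml_per_min > 0:
        raise ValidationError("baseline CBF must be > 0")
    return ReserveResult(cfvr=pv_hyper / pv_base,
                         cfr=hyper_flow.cbf_ml_per_min
                         / baseline_flow.cbf_ml_per_min)


@dataclass
class DopplerAnalysis:
    """Everything the Doppler pipeline produced for one recording."""

    strip: DopplerStrip
    peaks: PeakSet
    cycles: list[CardiacCycle]
    landmarks: list[CycleLandmarks]
    metrics: list[CycleMetrics]
    kept: list[int]
    rejections: list[Rejection]
    summary: SummaryTable
    envelope_mask: np.ndarray
    threshold: int


def metrics_frame(analysis: DopplerAnalysis) -> pd.DataFrame:
    """Per-cycle table: index, the 13 parameters, kept flag and reason."""
    reasons = {r.index: r.reason for r in analysis.rejections}
    rows = []
    for i, m in enumerate(analysis.metrics):
        row = {"cycle": i, **m.as_dict(),
               "kept": i in analysis.kept,
               "rejection_reason": reasons.get(i, "")}
        rows.append(row)
    return pd.DataFrame(rows)


def write_workbook(path: str | Path, analyses: dict[str, DopplerAnalysis],
                   diameters: dict[str, DiameterSummary] | None = None,
                   flows: dict[str, FlowResult] | None = None,
                   reserve: ReserveResult | None = None) -> None:
    """Write the XLSX workbook plus CSV mirrors alongside.

    One per-cycle sheet per condition, a summary sheet, and optional
    diameter and flow/reserve sheets.  Reading the files back reproduces
    the numbers to full double precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_dir = path.with_suffix("")
    csv_dir.mkdir(parents=True, exist_ok=True)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for cond, analysis in analyses.items():
            df = metrics_frame(analysis)
            df.to_excel(xl, sheet_name=f"cycles_{cond}", index=False)
            df.to_csv(csv_dir / f"cycles_{cond}.csv", index=False)
            s = analysis.summary.table.reset_index(names="metric")
            s.to_excel(xl, sheet_name=f"summary_{cond}", index=False)
            s.to_csv(csv_dir / f"summary_{cond}.csv", index=False)
        if diameters:
            rows = [{"condition": c, **vars(d)} for c, d in diameters.items()]
            df = pd.DataFrame(rows)
            df.to_excel(xl, sheet_name="diameters", index=False)
            df.to_csv(csv_dir / "diameters.csv", index=False)
        if flows:
            rows = [{"condition": c, "diameter_mm": f.diameter_mm,
                     "vti_mm": f.vti_mm, "hr_bpm": f.hr_bpm,
                     "cbf_ml_per_min": f.cbf_ml_per_min}
                    for c, f in flows.items()]
            if reserve is not None:
                rows.append({"condition": "reserve", "cfvr": reserve.cfvr,
                             "cfr": reserve.cfr})
            df = pd.DataFrame(rows)
            df.to_excel(xl, sheet_name="flow", index=False)
            df.to_csv(csv_dir / "flow.csv", index=False)


def _marker(rgb: np.ndarray, row: int, col: int, color: tuple,
            size: int = 1) -> None:
    h, w = rgb.shape[:2]
    r0, r1 = max(0, row - size), min(h, row + size + 1)
    c0, c1 = max(0, col - size), min(w, col + size + 1)
    rgb[r0:r1, c0:c1] = color


def render_annotated(analysis: DopplerAnalysis, path: str | Path) -> np.ndarray:
    """Write the strip PNG with landmarks and ECG peak bars drawn in.

    Landmarks use the conventional five colors; inserted and detected ECG
    peaks both draw as white vertical bars.  Undefined landmarks are
    simply omitted.  Returns the RGB array that was written.
    """
    import imageio.v3 as iio

    strip = analysis.strip
    cal = strip.calibration
    d0 = strip.layout.doppler_rows[0]
    rgb = np.stack([strip.image] * 3, axis=-1).astype(np.uint8)
    for col in analysis.peaks.columns:
        rgb[:, int(col)] = (255, 255, 255)
    for cyc, lm in zip(analysis.cycles, analysis.landmarks):
        def put(col_v: tuple[int, float] | None, key: str) -> None:
            if col_v is None:
                return
            col, v = col_v
            row = d0 + cal.baseline_row - int(round(v / cal.v_per_row))
            _marker(rgb, row, cyc.start_col + col, LANDMARK_COLORS[key])
        if not lm.defined:
            continue
        put(lm.diastolic_onset, "diastolic_onset")
        put(lm.peak, "peak")
        put(lm.decay_point, "decay_point")
        if lm.peak_decel is not None:
            pd_col = lm.peak_decel[0]
            v_at = float(cyc.trace.v[pd_col])
            put((pd_col, v_at), "peak_decel")
        end_row = d0 + cal.baseline_row
        _marker(rgb, end_row - 2, cyc.end_col - 1, LANDMARK_COLORS["end"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return rgb
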