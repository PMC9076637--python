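"""Vessel diameter measurement from B-mode/color-mode frames.

The coronary appears as a bright near-vertical band crossing the marked
center line of the color box.  Each frame is cropped around the center
line, rotated by the probe angle so the vessel stands vertical, globally
thresholded (the same Otsu machinery used for the Doppler envelope), and
reduced to connected components.  A component is accepted as the vessel
only if it is large enough and centered near the measurement axis — the
guard against speckle and ventricular filling — and its diameter is the
mean horizontal wall-to-wall distance converted to mm through the probe
depth calibration.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .envelope_extraction import (ValidationError, binarize, otsu_threshold)
from .video_ingest import FrameSequence


@dataclass(frozen=True)
class ProbeGeometry:
    """Probe angle and depth span; converts pixels to mm.

    ``mm_per_px`` assumes square pixels: the axial depth span
    ``depth_max_mm - depth_min_mm`` maps onto ``region_height_px`` rows.
    """

    angle_deg: float
    depth_min_mm: float
    depth_max_mm: float
    region_height_px: int

    def __post_init__(self) -> None:
        if not 0 <= self.angle_deg < 90:
            raise ValidationError("angle_deg must be in [0, 90)")
        if self.depth_max_mm <= self.depth_min_mm:
            raise ValidationError("depth_max_mm must exceed depth_min_mm")
        if self.region_height_px < 2:
            raise ValidationError("region_height_px must be >= 2")

    @property
    def mm_per_px(self) -> float:
        return (self.depth_max_mm - self.depth_min_mm) / self.region_height_px


@dataclass
class MeasurementAxis:
    """Crop window rows and the center-line column anchoring measurement."""

    row_window: tuple[int, int]
    center_col: int


@dataclass
class DiameterSummary:
    """The six diameter statistics over all measured frames, in mm."""

    min: float
    max: float
    mean: float
    median: float
    mode: float
    sd: float
    n_frames_measured: int


def locate_measurement_axis(first_frame: np.ndarray,
                            marker_rows: int = 10,
                            center_override: int | None = None,
                            ) -> MeasurementAxis:
    """Find the center-line marker and the vertical extent of the color box.

    The marker is the brightest column of the top ``marker_rows`` rows.
    With no marker present (flat top band) a ``center_override`` column
    must be supplied.  The row window spans the content between the top
    and bottom marker/border bands.
    """
    img = np.asarray(first_frame, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a 2-D grayscale frame")
    h, w = img.shape
    if center_override is not None:
        center = int(center_override)
    else:
        colsum = img[:marker_rows].sum(axis=0)
        if colsum.max() <= 2 * colsum.mean() + 1e-9:
            raise ValidationError(
                "center-line marker not found; pass the center column "
                "explicitly in the configuration")
        center = int(np.argmax(colsum))
    return MeasurementAxis(row_window=(marker_rows + 2, h - marker_rows - 2),
                           center_col=center)


def measure_frame(frame: np.ndarray, geom: ProbeGeometry,
                  axis: MeasurementAxis, min_area_px: int = 100,
                  location_tol_px: int = 15,
                  threshold_offset: int = 0) -> float | None:
    """Diameter of the vessel in one frame, in mm; None when absent.

    The crop around the center line is rotated by ``angle_deg`` so the
    vessel stands vertical, thresholded, and labeled; the largest
    component with area >= ``min_area_px`` whose centroid column lies
    within ``location_tol_px`` of the axis is measured as the mean over
    rows of (right wall - left wall + 1) pixels.  Rows near the component
    ends are trimmed to avoid corner-clipped partial widths.
    """
    img = np.asarray(frame, dtype=float)
    r0, r1 = axis.row_window
    half = (r1 - r0) // 2
    c0 = axis.center_col
    lo, hi = max(0, c0 - half), min(img.shape[1], c0 + half + 1)
    crop = img[r0:r1, lo:hi]
    if geom.angle_deg:
        crop = ndimage.rotate(crop, -geom.angle_deg, reshape=False,
                              order=1, mode="constant", cval=0.0)
    crop = np.clip(np.rint(crop), 0, 255).astype(np.uint8)
    try:
        thr = otsu_threshold(crop)
    except ValidationError:
        return None
    mask = binarize(crop, thr, threshold_offset).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    center_in_crop = c0 - lo
    best_label, best_area = None, 0
    for lab in range(1, n + 1):
        area = int((labels == lab).sum())
        if area < min_area_px:
            continue
        rows, cols = np.nonzero(labels == lab)
        if abs(float(cols.mean()) - center_in_crop) > location_tol_px:
            continue
        if area > best_area:
            best_label, best_area = lab, area
    if best_label is None:
        return None
    rows, cols = np.nonzero(labels == best_label)
    row_ids = np.unique(rows)
    trim = max(1, row_ids.size // 5)
    keep_rows = row_ids[trim:-trim] if row_ids.size > 2 * trim else row_ids
    widths = []
    for r in keep_rows:
        c = cols[rows == r]
        widths.append(c.max() - c.min() + 1)
    return float(np.mean(widths) * geom.mm_per_px)


def summarize_diameters(diameters: list[float]) -> DiameterSummary:
    """The six summary statistics of the per-frame diameters.

    The mode is computed on values rounded to 0.01 mm, with the smallest
    modal value taken on ties; a single measurement has sd 0.
    """
    vals = [float(d) for d in diameters if d is not None]
    if not vals:
        raise ValidationError("no frames yielded a diameter measurement")
    arr = np.array(vals)
    rounded = np.round(arr, 2)
    modes = statistics.multimode(rounded.tolist())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return DiameterSummary(
        min=float(arr.min()), max=float(arr.max()), mean=float(arr.mean()),
        median=float(np.median(arr)), mode=float(min(modes)), sd=sd,
        n_frames_measured=arr.size)


def measure_video(frames: FrameSequence, geom: ProbeGeometry,
                  min_area_px: int = 100, location_tol_px: int = 15,
                  threshold_offset: int = 0,
                  center_override: int | None = None,
                  ) -> tuple[DiameterSummary, list[float | None]]:
    """Measure every frame of a color-mode video and summarize."""
    axis = locate_measurement_axis(frames.frames[0],
                                   center_override=center_override)
    per_frame = [measure_frame(f, geom, axis, min_area_px=min_area_px,
                               location_tol_px=location_tol_px,
                               threshold_offset=threshold_offset)
                 for f in frames.frames]
    return summarize_diameters([d for d in per_frame if d is not None]), \
        per_frame
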