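"""Binarization of the spectral Doppler region and envelope tracing.

The spectral strip is an 8-bit grayscale image with time along the columns
and velocity along the rows (row 0 = top of the velocity scale, the
baseline row = zero velocity).  The envelope — the maximum-velocity contour
of the spectral signal — is recovered by smoothing, dilating and globally
thresholding the region, deleting noise objects that do not reach down to
the baseline (notably "top noise" hanging from the top of the window),
filling small holes, and reading the topmost foreground row per column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class CoroflowError(Exception):
    """Base class for validation and processing errors."""


class ValidationError(CoroflowError, ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Calibration:
    """Maps strip pixels to physical units.

    Parameters
    ----------
    scale_max_v:
        Velocity in mm/s at the top row of the Doppler region (the number
        printed at the top of the instrument's velocity scale).
    ms_per_px:
        Milliseconds of recording represented by one column.
    baseline_row:
        Row index (within the Doppler region) of the zero-velocity line.
    rows_above_baseline:
        Number of rows between the scale top and the baseline; defaults to
        ``baseline_row`` (scale top at row 0).
    """

    scale_max_v: float
    ms_per_px: float
    baseline_row: int
    rows_above_baseline: int = 0

    def __post_init__(self) -> None:
        if self.scale_max_v <= 0:
            raise ValidationError("scale_max_v must be > 0")
        if self.ms_per_px <= 0:
            raise ValidationError("ms_per_px must be > 0")
        if self.baseline_row <= 0:
            raise ValidationError("baseline_row must be > 0")
        if self.rows_above_baseline <= 0:
            object.__setattr__(self, "rows_above_baseline", self.baseline_row)

    @property
    def v_per_row(self) -> float:
        return self.scale_max_v / self.rows_above_baseline


@dataclass
class VelocityTrace:
    """Per-column envelope velocity.

    ``v`` holds non-negative velocities in mm/s, one per strip column;
    ``t`` the matching times in ms (uniform grid, step ``ms_per_px``).
    """

    v: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.v.shape != self.t.shape:
            raise ValidationError("v and t must have equal length")

    def __len__(self) -> int:
        return self.v.size


def _as_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("expected a 2-D grayscale image")
    return image


def preprocess(image: np.ndarray, gaussian_sigma_px: float = 1.0,
               dilation_len_px: int = 3) -> np.ndarray:
    """Gaussian-smooth then dilate with a horizontal linear element.

    The dilation element is 1 row by ``dilation_len_px`` columns, so it
    widens the signal along the time axis without lifting the envelope
    toward higher velocities.  The default length of 3 closes single-column
    dropouts while leaving the narrow diastolic-onset dip measurable (a
    wider element acts as a closing that fills it).  Output is 8-bit,
    same shape.
    """
    image = _as_gray(image)
    if gaussian_sigma_px < 0:
        raise ValidationError("gaussian_sigma_px must be >= 0")
    if dilation_len_px < 1:
        raise ValidationError("dilation_len_px must be >= 1")
    out = image.astype(float)
    if gaussian_sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma_px)
    if dilation_len_px > 1:
        out = ndimage.grey_dilation(out, size=(1, dilation_len_px))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's global threshold of the 256-bin histogram.

    Returns the integer threshold ``t`` maximizing the between-class
    variance of the split ``{<= t, > t}``.  Plateau ties resolve to the
    smallest maximizing threshold so runs are deterministic.
    """
    image = _as_gray(image)
    hist = np.bincount(image.astype(np.uint8).ravel(), minlength=256).astype(float)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValidationError("Otsu threshold undefined for a constant image")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)                      # pixels <= t
    m0 = np.cumsum(hist * levels)             # intensity mass <= t
    w1 = n - w0
    mu_total = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        between = w0 * w1 * (mean0 - mean1) ** 2
    between[~np.isfinite(between)] = -np.inf
    return int(np.argmax(between))            # argmax takes the first maximum


def binarize(image: np.ndarray, threshold: int, offset: int = 0) -> np.ndarray:
    """Binary mask ``image > threshold + offset``.

    ``offset`` is the non-interactive stand-in for the manual threshold
    adjustment step: a negative offset admits fainter signal, a positive
    offset removes more noise.  Raising the offset can only shrink the mask.
    """
    image = _as_gray(image)
    eff = threshold + offset
    if not 0 <= eff <= 255:
        raise ValidationError(
            f"effective threshold {eff} outside [0, 255]")
    return (image > eff).astype(np.uint8)


_STRUCT8 = np.ones((3, 3), dtype=int)   # 8-connectivity, as contours would see


def remove_noise(mask: np.ndarray, baseline_row: int,
                 proximity_px: int = 10) -> np.ndarray:
    """Delete connected components farther than ``proximity_px`` rows from
    the baseline.

    Every 8-connected foreground object whose nearest pixel is more than
    ``proximity_px`` rows from ``baseline_row`` is removed whole; objects
    reaching the baseline band are kept whole.  This removes top noise and
    any floating speckle while never clipping the flow envelope itself.
    """
    mask = _as_gray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.astype(np.uint8)
    rows = np.arange(mask.shape[0])
    rowdist = np.abs(rows - baseline_row)[:, None] * np.ones((1, mask.shape[1]))
    mindist = ndimage.minimum(rowdist, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(np.asarray(mindist) <= proximity_px) + 1
    return np.isin(labels, keep).astype(np.uint8)


def fill_holes(mask: np.ndarray, max_hole_area_px: int = 64) -> np.ndarray:
    """Fill enclosed background pockets of area <= ``max_hole_area_px``.

    A hole is a background component with no pixel on the image border.
    Border-connected background is never filled regardless of size.
    """
    mask = _as_gray(mask).astype(bool)
    bg_labels, n = ndimage.label(~mask)   # 4-connectivity for background
    if n == 0:
        return mask.astype(np.uint8)
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = np.unique(bg_labels[border & ~mask])
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=int), bg_labels,
                               index=np.arange(1, n + 1))
    fill = [i + 1 for i, a in enumerate(areas)
            if (i + 1) not in border_labels and a <= max_hole_area_px]
    out = mask.copy()
    if fill:
        out |= np.isin(bg_labels, fill)
    return out.astype(np.uint8)


def extract_trace(mask: np.ndarray, cal: Calibration) -> VelocityTrace:
    """Read the envelope as the topmost foreground row of each column.

    Velocity for a column with topmost foreground row ``r`` is
    ``(baseline_row - r) * scale_max_v / rows_above_baseline``; columns with
    no foreground (or foreground only below the baseline) read 0 mm/s.
    """
    mask = _as_gray(mask).astype(bool)
    h, w = mask.shape
    any_fg = mask.any(axis=0)
    top = np.where(any_fg, mask.argmax(axis=0), cal.baseline_row)
    v = (cal.baseline_row - top) * cal.v_per_row
    v = np.maximum(v, 0.0)
    t = np.arange(w) * cal.ms_per_px
    return VelocityTrace(v=v, t=t)


@dataclass
class EnvelopeResult:
    """Output bundle of the envelope pipeline."""

    mask: np.ndarray
    trace: VelocityTrace
    threshold: int
    offset: int


def extract_envelope(doppler: np.ndarray, cal: Calibration, *,
                     threshold_offset: int = 0,
                     gaussian_sigma_px: float = 1.0,
                     dilation_len_px: int = 3,
                     proximity_px: int = 10,
                     max_hole_area_px: int = 64) -> EnvelopeResult:
    """Full envelope pipeline: preprocess, Otsu + offset, clean, trace.

    Rows below the baseline are cleared before tracing: reverse (negative)
    flow is outside the scope of this analysis.
    """
    pre = preprocess(doppler, gaussian_sigma_px, dilation_len_px)
    thr = otsu_threshold(pre)
    off = int(np.clip(thr + threshold_offset, 0, 255)) - thr
    mask = binarize(pre, thr, off)
    mask[cal.baseline_row + 1:, :] = 0
    mask = remove_noise(mask, cal.baseline_row, proximity_px)
    mask = fill_holes(mask, max_hole_area_px)
    trace = extract_trace(mask, cal)
    return EnvelopeResult(mask=mask, trace=trace, threshold=thr, offset=off)
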