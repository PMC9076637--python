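"""Per-cycle landmark location and hemodynamic parameter extraction.

Murine coronary flow is diastole-dominant: each cycle shows a small
systolic bump, a dip at diastolic onset, a steep rise to the diastolic
peak, a slow decay to the decay point, and a sharp fall to near zero at
the next QRS.  Five landmarks are located on the envelope of every cycle —
diastolic onset, peak, decay point, peak diastolic deceleration, and cycle
end — and from them eleven parameters are computed: three velocities, four
segment durations, four segment slopes, plus heart rate and the
velocity-time integral (VTI).

Landmark definitions the instrument literature leaves open are fixed here
and documented: systolic rise time runs from cycle start to the systolic
bump maximum; decay time/slope 1 covers peak to decay point, 2 covers
decay point to cycle end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .ecg_segmentation import CardiacCycle
from .envelope_extraction import Calibration, ValidationError

#: Velocity units are mm/s while the time axis is in ms; slopes are
#: reported in mm/s^2, hence the factor 1000 on every dv/dt.
MS_TO_S = 1000.0


@dataclass
class CycleLandmarks:
    """The five landmark points of one cycle, columns cycle-relative.

    ``systolic_peak`` is None when no systolic bump exists (faint systole);
    dependent metrics are then undefined rather than fabricated.
    ``defined`` is False for degenerate (flat or monotone) cycles, which
    are reported but excluded from summaries.
    """

    diastolic_onset: tuple[int, float] | None
    peak: tuple[int, float] | None
    decay_point: tuple[int, float] | None
    peak_decel: tuple[int, float] | None
    end_col: int
    systolic_peak: tuple[int, float] | None = None
    defined: bool = True


@dataclass
class CycleMetrics:
    """The extracted parameters of one cardiac cycle (NaN = undefined)."""

    peak_velocity: float = math.nan        # mm/s
    diastolic_velocity: float = math.nan   # mm/s
    decay_velocity: float = math.nan       # mm/s
    systolic_rise_time: float = math.nan   # ms
    diastolic_rise_time: float = math.nan  # ms
    diastolic_decay_time_1: float = math.nan  # ms
    diastolic_decay_time_2: float = math.nan  # ms
    systolic_slope: float = math.nan       # mm/s^2
    diastolic_slope: float = math.nan      # mm/s^2
    decay_slope_1: float = math.nan        # mm/s^2
    decay_slope_2: float = math.nan        # mm/s^2
    heart_rate: float = math.nan           # BPM
    vti: float = math.nan                  # mm

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _acceleration(v: np.ndarray, ms_per_px: float) -> np.ndarray:
    """Centered first difference of velocity, in mm/s^2."""
    return np.gradient(v) / ms_per_px * MS_TO_S


def _refine(raw: np.ndarray, i: int, half: int, find_max: bool) -> int:
    """Snap a smoothed-trace landmark to the raw extremum within +-half.

    Box smoothing drags the extremum of an asymmetric peak or dip toward
    its shallower limb; re-locating on the raw trace removes that bias.
    """
    lo, hi = max(0, i - half), min(raw.size, i + half + 1)
    seg = raw[lo:hi]
    return lo + int(np.argmax(seg) if find_max else np.argmin(seg))


def locate_landmarks(cycle: CardiacCycle,
                     smooth_win_px: int = 5) -> CycleLandmarks:
    """Locate the five landmarks on the (smoothed) cycle envelope.

    The trace is box-smoothed before differentiation; landmark velocities
    are read from the raw trace at the located columns so smoothing does
    not bias the reported values.  The decay point is taken as the
    acceleration zero-crossing nearest peak deceleration when one exists
    away from the peak; on a cleanly monotone decay (no crossing) the
    deceleration knee — the minimum of the acceleration's derivative after
    the peak — marks where the terminal plunge sets in.
    """
    raw = cycle.trace.v
    n = raw.size
    if n < 8:
        raise ValidationError("cycle too short to analyze (need >= 8 columns)")
    ms = cycle.ms_per_px
    v = uniform_filter1d(raw, size=max(1, smooth_win_px), mode="nearest")
    if not np.isfinite(v).all() or v.max() <= 0 or np.ptp(v) == 0:
        return CycleLandmarks(None, None, None, None, end_col=n, defined=False)

    half = max(1, smooth_win_px // 2)
    peak_i = _refine(raw, int(np.argmax(v)), half, find_max=True)
    peak = (peak_i, float(raw[peak_i]))

    # Systolic bump: first local maximum strictly before the global peak.
    sys_peak = None
    if peak_i >= 2:
        bumps, _ = find_peaks(v[:peak_i])
        if bumps.size:
            b = _refine(raw, int(bumps[0]), half, find_max=True)
            sys_peak = (b, float(raw[b]))

    # Diastolic onset: deepest local minimum between bump and peak, else
    # the earliest rise point of the cycle.
    if sys_peak is not None and peak_i - sys_peak[0] >= 2:
        seg = v[sys_peak[0]:peak_i + 1]
        onset_i = sys_peak[0] + int(np.argmin(seg))
        onset_i = _refine(raw, onset_i, half, find_max=False)
        onset_i = min(onset_i, peak_i)
    else:
        rising = np.flatnonzero(np.diff(v[:peak_i + 1]) > 0)
        onset_i = int(rising[0]) if rising.size else 0
    onset = (onset_i, float(raw[onset_i]))

    a = _acceleration(v, ms)
    search = peak_i + max(1, smooth_win_px)
    if search >= n - 1 or peak_i == 0:
        return CycleLandmarks(onset, peak, None, None, end_col=n,
                              systolic_peak=sys_peak, defined=False)
    pd_i = search + int(np.argmin(a[search:n - 1]))
    pd = (pd_i, float(a[pd_i]))

    # Decay point: where the deceleration episode around peak deceleration
    # sets in.  When the acceleration genuinely switched sign there (the
    # envelope shoulders or briefly rises before the terminal plunge), the
    # start of the negative-acceleration run containing peak deceleration
    # is that crossing; a shoulder is only believed if its positive
    # excursion is a substantial fraction of the peak deceleration, so
    # quantization flicker cannot masquerade as one.  On a cleanly
    # monotone decay the deceleration knee — the steepest increase of
    # deceleration after the peak — marks the same landmark.
    run_start = pd_i
    while run_start > search and a[run_start - 1] < 0:
        run_start -= 1
    shoulder = a[max(search, run_start - 3):run_start + 1]
    if run_start > search and shoulder.size and \
            shoulder.max() > 0.15 * abs(a[pd_i]):
        decay_i = run_start
    else:
        # The knee window skips two smoothing windows past the peak: the
        # peak's own acceleration ramp spans about one window, and the
        # raw-refined peak can sit half a window left of the smoothed apex.
        knee_lo = min(n - 2, peak_i + 2 * max(1, smooth_win_px))
        knee_hi = max(knee_lo + 1, pd_i + 1)
        jerk = np.gradient(a)
        decay_i = knee_lo + int(np.argmin(jerk[knee_lo:knee_hi]))
    decay = (decay_i, float(raw[decay_i]))
    return CycleLandmarks(onset, peak, decay, pd, end_col=n,
                          systolic_peak=sys_peak, defined=True)


def compute_vti(cycle: CardiacCycle, cal: Calibration | None = None) -> float:
    """Velocity-time integral of the cycle, in mm.

    Each column contributes its velocity (mm/s) times the column width
    (ms); the trapezoid sum over the column grid therefore reduces to
    ``sum(v) * ms_per_px / 1000``, exact for the rendered sampling.
    """
    v = cycle.trace.v
    if np.any(v < 0):
        raise ValidationError("velocity trace must be non-negative")
    return float(v.sum() * cycle.ms_per_px / MS_TO_S)


def compute_metrics(cycle: CardiacCycle, lm: CycleLandmarks,
                    cal: Calibration) -> CycleMetrics:
    """Compute the eleven parameters from the located landmarks.

    Times are column spans times ``ms_per_px``; slopes are velocity
    differences over those spans in mm/s^2; heart rate comes from the full
    cycle duration and VTI from the column-sum integral.  Any segment of
    zero duration leaves its metric undefined (NaN).
    """
    m = CycleMetrics()
    ms = cycle.ms_per_px
    n = cycle.n_columns
    m.heart_rate = 60000.0 / (n * ms)
    raw = cycle.trace.v
    if not lm.defined or lm.peak is None:
        return m
    m.vti = compute_vti(cycle, cal)
    peak_i, peak_v = lm.peak
    m.peak_velocity = peak_v
    if lm.diastolic_onset is not None:
        onset_i, onset_v = lm.diastolic_onset
        m.diastolic_velocity = onset_v
        if peak_i > onset_i:
            m.diastolic_rise_time = (peak_i - onset_i) * ms
            m.diastolic_slope = ((peak_v - onset_v)
                                 / m.diastolic_rise_time * MS_TO_S)
    if lm.systolic_peak is not None:
        sys_i, sys_v = lm.systolic_peak
        if sys_i > 0:
            m.systolic_rise_time = sys_i * ms
            # The envelope leaves the baseline (zero velocity) at the QRS,
            # so the systolic rise is measured from zero at cycle start.
            m.systolic_slope = sys_v / m.systolic_rise_time * MS_TO_S
    if lm.decay_point is not None:
        decay_i, decay_v = lm.decay_point
        m.decay_velocity = decay_v
        if decay_i > peak_i:
            m.diastolic_decay_time_1 = (decay_i - peak_i) * ms
            m.decay_slope_1 = ((decay_v - peak_v)
                               / m.diastolic_decay_time_1 * MS_TO_S)
        if n > decay_i:
            m.diastolic_decay_time_2 = (n - decay_i) * ms
            m.decay_slope_2 = ((float(raw[-1]) - decay_v)
                               / m.diastolic_decay_time_2 * MS_TO_S)
    return m


def analyze_cycle(cycle: CardiacCycle, cal: Calibration,
                  smooth_win_px: int = 5) -> tuple[CycleLandmarks, CycleMetrics]:
    """Convenience: landmarks plus metrics for one cycle."""
    lm = locate_landmarks(cycle, smooth_win_px=smooth_win_px)
    return lm, compute_metrics(cycle, lm, cal)
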