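"""Seeded generator of Doppler strips, scrolling videos and color-mode
frames with exact analytic ground truth.

No public Doppler echocardiography dataset accompanies this kind of
analysis, so every stage is validated against synthetic recordings whose
true parameters are known in closed form.  Each cardiac cycle is a
piecewise-linear envelope through six vertices — cycle start, systolic
bump, diastolic onset, diastolic peak, decay point, cycle end — which
reproduces the diastole-dominant murine coronary waveform while keeping
every one of the eleven per-cycle parameters analytically computable.
Artifacts seen in real recordings are emulated explicitly: background
speckle, "top noise" blobs hanging from the top of the Doppler window,
faint (low-brightness) cycles, and low-amplitude unrepresentative cycles.

Default waveform proportions and amplitudes are modeled on published
murine transthoracic Doppler values (baseline peak velocity ~290 mm/s at
~360 BPM with VTI ~22 mm; hyperemia ~850 mm/s, VTI ~60 mm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cycle_metrics import CycleMetrics
from .ecg_segmentation import CardiacCycle
from .envelope_extraction import Calibration, ValidationError, VelocityTrace
from .strip_io import DopplerStrip
from .video_ingest import FrameSequence, RegionLayout

# Waveform shape constants (fractions of the systolic / diastolic portions).
SYS_BUMP_FRAC = 0.85    # systolic bump position within the systolic portion
DIA_RISE_FRAC = 0.25    # diastolic onset -> peak, fraction of diastole
DIA_DECAY_FRAC = 0.67   # diastolic onset -> decay point, fraction of diastole
END_V_FRAC = 0.02       # end-of-cycle velocity as a fraction of peak_v

#: Lead-in/lead-out of zero flow so every QRS spike is an interior column.
PAD_PX = 16

FAINT_INTENSITY_CUTOFF = 0.75
LOW_AMPLITUDE_CUTOFF = 0.5   # of the median peak velocity


@dataclass(frozen=True)
class CycleSpec:
    """Analytic description of one cardiac cycle's envelope."""

    duration_ms: float
    peak_v: float
    systolic_peak_v: float
    diastolic_onset_v: float
    decay_v: float
    intensity: float = 1.0
    systolic_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValidationError("duration_ms must be > 0")
        if self.peak_v <= 0:
            raise ValidationError("peak_v must be > 0")
        for name in ("systolic_peak_v", "diastolic_onset_v", "decay_v"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.diastolic_onset_v > self.peak_v:
            raise ValidationError("peak_v must be >= diastolic_onset_v")
        if self.decay_v > self.peak_v:
            raise ValidationError("peak_v must be >= decay_v")
        if not 0 < self.intensity <= 1:
            raise ValidationError("intensity must be in (0, 1]")
        if not 0 < self.systolic_fraction < 1:
            raise ValidationError("systolic_fraction must be in (0, 1)")

    def vertices(self) -> tuple[np.ndarray, np.ndarray]:
        """Vertex times (ms, cycle-relative) and velocities (mm/s)."""
        T = self.duration_ms
        sys_t = self.systolic_fraction * T
        dia = T - sys_t
        t = np.array([0.0, SYS_BUMP_FRAC * sys_t, sys_t,
                      sys_t + DIA_RISE_FRAC * dia,
                      sys_t + DIA_DECAY_FRAC * dia, T])
        v = np.array([0.0, self.systolic_peak_v, self.diastolic_onset_v,
                      self.peak_v, self.decay_v, END_V_FRAC * self.peak_v])
        return t, v

    def velocity_at(self, t_ms: np.ndarray) -> np.ndarray:
        tv, vv = self.vertices()
        return np.interp(np.asarray(t_ms, dtype=float), tv, vv)

    def true_metrics(self) -> CycleMetrics:
        """The eleven parameters, computed exactly from the vertices."""
        (t0, t1, t2, t3, t4, t5), (v0, v1, v2, v3, v4, v5) = self.vertices()
        vti = float(np.trapezoid(self.vertices()[1], self.vertices()[0])) / 1e3
        return CycleMetrics(
            peak_velocity=v3,
            diastolic_velocity=v2,
            decay_velocity=v4,
            systolic_rise_time=t1 - t0,
            diastolic_rise_time=t3 - t2,
            diastolic_decay_time_1=t4 - t3,
            diastolic_decay_time_2=t5 - t4,
            systolic_slope=(v1 - v0) / (t1 - t0) * 1e3,
            diastolic_slope=(v3 - v2) / (t3 - t2) * 1e3,
            decay_slope_1=(v4 - v3) / (t4 - t3) * 1e3,
            decay_slope_2=(v5 - v4) / (t5 - t4) * 1e3,
            heart_rate=60000.0 / self.duration_ms,
            vti=vti,
        )


@dataclass(frozen=True)
class StripSpec:
    """Full description of a synthetic Doppler strip."""

    cycles: tuple[CycleSpec, ...]
    scale_max_v: float
    ms_per_px: float = 0.5
    px_height_doppler: int = 220
    px_height_ecg: int = 44
    baseline_row: int = 200
    noise_blobs: tuple[tuple[int, int, int, int], ...] = ()
    speckle_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", tuple(self.cycles))
        object.__setattr__(self, "noise_blobs",
                           tuple(tuple(b) for b in self.noise_blobs))
        if not self.cycles:
            raise ValidationError("cycles must be non-empty")
        if self.ms_per_px <= 0:
            raise ValidationError("ms_per_px must be > 0")
        if self.scale_max_v < max(c.peak_v for c in self.cycles):
            raise ValidationError("scale_max_v must cover the largest peak_v")
        if not 0 < self.baseline_row < self.px_height_doppler:
            raise ValidationError(
                "baseline_row must lie inside the Doppler region")
        w = self.width
        for row, col, radius, _ in self.noise_blobs:
            if not (0 <= row < self.px_height_doppler and 0 <= col < w):
                raise ValidationError(
                    "noise_blobs centers must lie inside the Doppler region")
            if radius < 1:
                raise ValidationError("noise_blobs radius must be >= 1")

    @property
    def cycle_bounds(self) -> np.ndarray:
        """Column boundaries of the cycles, including both pads."""
        ncols = [int(round(c.duration_ms / self.ms_per_px))
                 for c in self.cycles]
        return PAD_PX + np.concatenate([[0], np.cumsum(ncols)])

    @property
    def width(self) -> int:
        return int(self.cycle_bounds[-1]) + PAD_PX

    @property
    def calibration(self) -> Calibration:
        return Calibration(scale_max_v=self.scale_max_v,
                           ms_per_px=self.ms_per_px,
                           baseline_row=self.baseline_row,
                           rows_above_baseline=self.baseline_row)

    @property
    def layout(self) -> RegionLayout:
        h = self.px_height_doppler
        return RegionLayout(doppler_rows=(0, h),
                            ecg_rows=(h, h + self.px_height_ecg))


@dataclass
class GroundTruth:
    """Exact per-cycle truth emitted alongside each synthetic strip."""

    metrics: list[CycleMetrics]
    cycle_bounds: np.ndarray          # n_cycles + 1 columns
    ecg_peaks: np.ndarray             # == cycle_bounds (one QRS per bound)
    mask: np.ndarray                  # true envelope mask, Doppler region
    velocity: np.ndarray              # true per-column velocity, mm/s
    landmark_cols: list[dict[str, int]]   # cycle-relative vertex columns
    faint: list[bool]
    low_amplitude: list[bool]

    @property
    def n_cycles(self) -> int:
        return len(self.metrics)

    def trace(self, ms_per_px: float) -> VelocityTrace:
        t = np.arange(self.velocity.size) * ms_per_px
        return VelocityTrace(v=self.velocity.copy(), t=t)


def _render_ecg(width: int, height: int, peak_cols: np.ndarray) -> np.ndarray:
    ecg = np.zeros((height, width), dtype=np.uint8)
    base = height - 4
    ecg[base, :] = 255
    spike_h = int(round(0.75 * height))
    for b in peak_cols:
        for d in range(-3, 4):
            c = int(b) + d
            if 0 <= c < width:
                top = base - int(round(spike_h * (1 - abs(d) / 4)))
                ecg[max(top, 0):base, c] = 255
    return ecg


def generate_strip(spec: StripSpec) -> tuple[DopplerStrip, GroundTruth]:
    """Render a strip and its exact ground truth.

    Deterministic for a fixed ``spec.seed``; the envelope is drawn at
    ``255 * intensity`` before speckle; one QRS spike sits at every cycle
    boundary (n_cycles + 1 spikes, counting both ends); noise blobs are
    painted into the image only, never into the truth.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = spec.cycle_bounds
    width = spec.width
    hd, he = spec.px_height_doppler, spec.px_height_ecg
    cal = spec.calibration

    doppler = np.zeros((hd, width), dtype=float)
    mask = np.zeros((hd, width), dtype=np.uint8)
    velocity = np.zeros(width, dtype=float)
    metrics, landmark_cols = [], []

    for k, cyc in enumerate(spec.cycles):
        a, b = int(bounds[k]), int(bounds[k + 1])
        t_local = (np.arange(b - a) + 0.5) * spec.ms_per_px
        v = cyc.velocity_at(t_local)
        velocity[a:b] = v
        top = cal.baseline_row - np.round(v / cal.v_per_row).astype(int)
        top = np.clip(top, 0, cal.baseline_row)
        level = int(round(255 * cyc.intensity))
        for j in range(b - a):
            if top[j] < cal.baseline_row:
                doppler[top[j]:cal.baseline_row, a + j] = level
                mask[top[j]:cal.baseline_row, a + j] = 1
        metrics.append(cyc.true_metrics())
        tv, _ = cyc.vertices()
        landmark_cols.append({
            "systolic_peak": int(round(tv[1] / spec.ms_per_px - 0.5)),
            "diastolic_onset": int(round(tv[2] / spec.ms_per_px - 0.5)),
            "peak": int(round(tv[3] / spec.ms_per_px - 0.5)),
            "decay_point": int(round(tv[4] / spec.ms_per_px - 0.5)),
        })

    for row, col, radius, intensity in spec.noise_blobs:
        rr, cc = np.ogrid[:hd, :width]
        disk = (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2
        doppler[disk] = np.maximum(doppler[disk], intensity)

    ecg = _render_ecg(width, he, bounds).astype(float)
    image = np.vstack([doppler, ecg])
    if spec.speckle_sd > 0:
        image = image + rng.normal(0.0, spec.speckle_sd, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    peaks_v = np.array([c.peak_v for c in spec.cycles])
    med = float(np.median(peaks_v))
    truth = GroundTruth(
        metrics=metrics,
        cycle_bounds=bounds.copy(),
        ecg_peaks=bounds.copy(),
        mask=mask,
        velocity=velocity,
        landmark_cols=landmark_cols,
        faint=[c.intensity < FAINT_INTENSITY_CUTOFF for c in spec.cycles],
        low_amplitude=[c.peak_v < LOW_AMPLITUDE_CUTOFF * med
                       for c in spec.cycles],
    )
    strip = DopplerStrip(image=image, layout=spec.layout, calibration=cal)
    return strip, truth


def render_scroll_video(strip: DopplerStrip | np.ndarray, frame_width_px: int,
                        sweep_px_per_frame: int) -> FrameSequence:
    """Emulate the console's sweeping cursor over a finished strip.

    The cursor paints ``sweep_px_per_frame`` new columns per frame over the
    previous sweep's content and wraps to the left edge after reaching the
    right edge.  After the final completed sweep one trailing frame is
    emitted in which the cursor wraps and paints a background band, so
    every completed sweep is delimited by an observable reset.  A trailing
    partial sweep (strip width not a multiple of the frame width) is
    painted as far as the data reaches and is dropped by stitching.
    """
    img = strip.image if isinstance(strip, DopplerStrip) else np.asarray(strip)
    if img.ndim != 2:
        raise ValidationError("strip must be a 2-D grayscale image")
    h, width = img.shape
    W = int(frame_width_px)
    if W < 1 or width == 0:
        raise ValidationError("frame_width_px must be >= 1")
    if W > width:
        raise ValidationError("frame_width_px must not exceed strip width")
    if sweep_px_per_frame < 1:
        raise ValidationError("sweep_px_per_frame must be >= 1")

    frames: list[np.ndarray] = []
    prev = np.zeros((h, W), dtype=np.uint8)
    n_full, leftover = divmod(width, W)
    for s in range(n_full):
        seg = img[:, s * W:(s + 1) * W]
        c = sweep_px_per_frame
        while True:
            cc = min(c, W)
            f = prev.copy()
            f[:, :cc] = seg[:, :cc]
            frames.append(f)
            if cc == W:
                break
            c += sweep_px_per_frame
        prev = seg.astype(np.uint8)
    if leftover:
        part = img[:, n_full * W:]
        c = sweep_px_per_frame
        while True:
            cc = min(c, leftover)
            f = prev.copy()
            f[:, :cc] = part[:, :cc]
            frames.append(f)
            if cc == leftover:
                break
            c += sweep_px_per_frame
    else:
        f = prev.copy()
        f[:, :min(sweep_px_per_frame, W)] = 0
        frames.append(f)
    return FrameSequence(frames=frames)


def generate_colormode_frames(vessel_width_px: int, angle_deg: float,
                              n_frames: int, depth_min_mm: float,
                              depth_max_mm: float, px_height: int = 256,
                              seed: int = 0, speckle_sd: float = 5.0,
                              ) -> tuple[FrameSequence, float]:
    """Synthetic B-mode/color frames with one bright vessel band.

    Each square frame holds a band of perpendicular width
    ``vessel_width_px`` tilted ``angle_deg`` from vertical and crossing the
    marked center line; the band is inset from the top and bottom edges
    (the color box never touches the window border) and a bright center
    marker tick is drawn in the top rows.  The true diameter is
    ``vessel_width_px * (depth_max_mm - depth_min_mm) / px_height`` mm,
    independent of the angle.
    """
    if not 0 <= angle_deg <= 45:
        raise ValidationError("angle_deg must be in [0, 45]")
    if depth_max_mm <= depth_min_mm:
        raise ValidationError("depth_max_mm must exceed depth_min_mm")
    if n_frames < 2:
        raise ValidationError("need n_frames >= 2")
    if vessel_width_px < 2:
        raise ValidationError("vessel_width_px must be >= 2")
    h = int(px_height)
    w = h
    c0, r0 = w // 2, h // 2
    inset = 12
    theta = np.deg2rad(angle_deg)
    max_off = np.tan(theta) * (h / 2 - inset) + vessel_width_px / (
        2 * np.cos(theta))
    if c0 - max_off < 1 or c0 + max_off > w - 1:
        raise ValidationError("vessel band falls outside the frame")

    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[:h, :w]
    frames = []
    for _ in range(n_frames):
        jitter = int(rng.integers(-1, 2))
        sd = (rr - r0) * np.sin(theta) - (cc - (c0 + jitter)) * np.cos(theta)
        # Half-open band so the perpendicular width is exactly w pixels.
        band = (sd >= -vessel_width_px / 2) & (sd < vessel_width_px / 2) \
            & (rr >= inset) & (rr < h - inset)
        f = np.zeros((h, w), dtype=float)
        f[band] = 200.0
        f[0:8, c0] = 255.0          # center-line marker ticks
        f[h - 8:h, c0] = 255.0
        if speckle_sd > 0:
            f = f + rng.normal(0.0, speckle_sd, f.shape)
        frames.append(np.clip(np.rint(f), 0, 255).astype(np.uint8))
    true_d = vessel_width_px * (depth_max_mm - depth_min_mm) / px_height
    return FrameSequence(frames=frames), float(true_d)


# ---------------------------------------------------------------------------
# Canned study conditions

_CONDITIONS = {
    # duration_ms, peak_v, scale_max_v — murine left coronary values
    "baseline": (165.0, 290.0, 400.0),
    "hyperemia": (160.0, 850.0, 1100.0),
}


def default_cycle(duration_ms: float, peak_v: float,
                  intensity: float = 1.0) -> CycleSpec:
    """A physiologically proportioned cycle for a given peak velocity."""
    return CycleSpec(duration_ms=duration_ms, peak_v=peak_v,
                     systolic_peak_v=0.35 * peak_v,
                     diastolic_onset_v=0.25 * peak_v,
                     decay_v=0.65 * peak_v,
                     intensity=intensity, systolic_fraction=0.4)


def default_strip_spec(condition: str = "baseline", n_cycles: int = 14,
                       seed: int = 0, faint: tuple[int, ...] = (),
                       low: tuple[int, ...] = (), low_scale: float = 0.4,
                       faint_intensity: float = 0.5,
                       speckle_sd: float = 8.0,
                       jitter: float = 0.03) -> StripSpec:
    """Standard study-condition strip with optional planted anomalies.

    ``faint`` lists cycle indices rendered at ``faint_intensity`` (dim but
    hemodynamically normal); ``low`` lists indices whose whole waveform is
    scaled by ``low_scale`` (unrepresentative cycles: the artery transiently
    out of the probe's view).  Beat-to-beat variability is lognormal-free
    mild Gaussian jitter on duration and amplitude.
    """
    if condition not in _CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    dur0, peak0, scale = _CONDITIONS[condition]
    rng = np.random.default_rng(seed)
    cycles = []
    for i in range(n_cycles):
        dur = dur0 * float(1 + jitter * rng.standard_normal())
        peak = peak0 * float(1 + jitter * rng.standard_normal())
        peak = min(peak, 0.95 * scale)
        if i in low:
            peak *= low_scale
        intensity = faint_intensity if i in faint else 1.0
        cycles.append(default_cycle(dur, peak, intensity=intensity))
    return StripSpec(cycles=tuple(cycles), scale_max_v=scale,
                     speckle_sd=speckle_sd, seed=seed)


def add_top_noise(spec: StripSpec, n_blobs: int = 3, seed: int | None = None,
                  intensity: int = 220) -> StripSpec:
    """Plant bright blobs descending from the top of the Doppler window.

    Blobs sit in the top rows, well above the highest envelope excursion,
    so they never merge with the flow signal and the truth is unchanged.
    """
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    width = spec.width
    blobs = list(spec.noise_blobs)
    for _ in range(n_blobs):
        radius = int(rng.integers(5, 9))
        row = int(rng.integers(radius, 19))
        col = int(rng.integers(30, width - 30))
        blobs.append((row, col, radius, intensity))
    return dataclasses.replace(spec, noise_blobs=tuple(blobs))
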