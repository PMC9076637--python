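"""End-to-end analysis: strip (or video) in, parameter tables out."""

from __future__ import annotations

import logging
import time

import numpy as np

from . import ecg_segmentation as ecg
from . import envelope_extraction as env
from .cycle_filter import FilterConfig, filter_and_summarize
from .cycle_metrics import analyze_cycle
from .flow_summary import DopplerAnalysis
from .strip_io import DopplerStrip
from .video_ingest import (FrameSequence, RegionLayout, crop_regions,
                           detect_sweep_resets, stitch_frames)

log = logging.getLogger("coroflow")


def strip_from_video(frames: FrameSequence, layout: RegionLayout,
                     calibration: env.Calibration) -> DopplerStrip:
    """Stitch a scrolling video into a continuous DopplerStrip."""
    t0 = time.perf_counter()
    resets = detect_sweep_resets(frames)
    image = stitch_frames(frames, resets)
    log.info("stitched %d frames (%d sweeps) in %.2fs", len(frames),
             max(len(resets), 1), time.perf_counter() - t0)
    return DopplerStrip(image=image, layout=layout, calibration=calibration)


def analyze_strip(strip: DopplerStrip, *, threshold_offset: int = 0,
                  filter_config: FilterConfig = FilterConfig(),
                  smooth_win_px: int = 5,
                  min_height_frac: float = 0.4,
                  min_distance_px: int | None = None,
                  expected_interval_px: int | None = None,
                  ) -> DopplerAnalysis:
    """Run the full Doppler pipeline on a continuous strip.

    Envelope extraction -> ECG peak detection and correction -> cycle
    segmentation -> per-cycle landmarks and metrics -> rejection of
    unrepresentative cycles -> summary statistics.
    """
    t0 = time.perf_counter()
    doppler, ecg_img = crop_regions(strip.image, strip.layout)
    cal = strip.calibration

    result = env.extract_envelope(doppler, cal,
                                  threshold_offset=threshold_offset)
    log.info("envelope threshold %d (offset %d)", result.threshold,
             result.offset)

    profile = ecg.ecg_profile(ecg_img)
    if min_distance_px is None:
        if expected_interval_px is None:
            # Expect HRs in the few-hundred-BPM range: a generous floor.
            min_distance_px = 8
        else:
            min_distance_px = max(8, int(0.3 * expected_interval_px))
    peaks = ecg.detect_peaks(profile, min_height_frac=min_height_frac,
                             min_distance_px=min_distance_px)
    peaks = ecg.correct_peaks(peaks, width=strip.width)
    cycles = ecg.segment_cycles(result.trace, peaks)

    landmarks, metrics = [], []
    for cyc in cycles:
        lm, m = analyze_cycle(cyc, cal, smooth_win_px=smooth_win_px)
        landmarks.append(lm)
        metrics.append(m)
    kept, rejections, summary = filter_and_summarize(metrics, filter_config)
    log.info("analyzed %d cycles (%d kept) in %.2fs", len(cycles), len(kept),
             time.perf_counter() - t0)
    return DopplerAnalysis(strip=strip, peaks=peaks, cycles=cycles,
                           landmarks=landmarks, metrics=metrics, kept=kept,
                           rejections=rejections, summary=summary,
                           envelope_mask=result.mask,
                           threshold=result.threshold)
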