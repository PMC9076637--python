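"""Turning a scrolling Doppler video into one continuous strip.

Clinical Doppler consoles draw the spectrogram with a sweeping cursor: new
columns are painted left to right and the cursor wraps ("resets") back to
the left edge when it reaches the right side of the window.  A recording
therefore contains each time segment twice over — partially painted while
the sweep is in progress and fully painted in the last frame of the sweep.
Stitching keeps one fully painted frame per sweep and concatenates them
into a single continuous strip.

Coordinates are 0-based, row 0 at the top; row intervals are half-open.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .envelope_extraction import ValidationError


@dataclass
class FrameSequence:
    """An ordered stack of same-shape 8-bit grayscale frames."""

    frames: list[np.ndarray]
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValidationError("a video needs at least 2 frames")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.ndim != 2 or f.shape != shape:
                raise ValidationError("all frames must be 2-D and same shape")
        if shape[1] == 0 or shape[0] == 0:
            raise ValidationError("frames must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class RegionLayout:
    """Row layout of the instrument window: Doppler and ECG bands.

    ``doppler_rows`` and ``ecg_rows`` are half-open ``(start, stop)`` row
    intervals; ``scale_col`` optionally marks the velocity-scale column.
    """

    doppler_rows: tuple[int, int]
    ecg_rows: tuple[int, int]
    scale_col: int | None = None

    def __post_init__(self) -> None:
        d0, d1 = self.doppler_rows
        e0, e1 = self.ecg_rows
        if not (0 <= d0 < d1):
            raise ValidationError("doppler_rows must be a non-empty interval")
        if not (0 <= e0 < e1):
            raise ValidationError("ecg_rows must be a non-empty interval")
        if max(d0, e0) < min(d1, e1):
            raise ValidationError("doppler_rows and ecg_rows must be disjoint")


def read_frames(path: str | Path) -> FrameSequence:
    """Read a video as a directory of sequentially numbered PNG frames.

    Frames are sorted by the first integer in each filename.  AVI input is
    not supported in this build (no codec plugin); convert to PNG frames
    first, e.g. ``ffmpeg -i video.avi frames/%05d.png``.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_file():
        raise ValidationError(
            "compressed video decoding is unavailable; supply a directory "
            "of numbered PNG frames instead")
    files = sorted(path.glob("*.png"),
                   key=lambda p: int(re.search(r"\d+", p.stem).group()))
    if not files:
        raise ValidationError(f"no PNG frames found in {path}")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[..., :3].mean(axis=2)
        frames.append(np.asarray(img, dtype=np.uint8))
    return FrameSequence(frames=frames)


def _diff_band(a: np.ndarray, b: np.ndarray) -> tuple[int, int] | None:
    """Column extent (start, stop] of change between two frames, or None."""
    colchange = np.abs(b.astype(int) - a.astype(int)).sum(axis=0)
    changed = np.flatnonzero(colchange > 0)
    if changed.size == 0:
        return None
    return int(changed[0]), int(changed[-1]) + 1


def detect_sweep_resets(frames: FrameSequence) -> list[int]:
    """Indices of frames in which the sweep cursor wrapped to the left.

    A reset is declared at frame ``i`` when the band of changed columns
    between frames ``i-1`` and ``i`` starts in the left margin of the
    window while the previous paint activity had reached the right margin
    — i.e. the cursor jumped from the right edge back to the left edge.
    On an all-static video an empty list is returned with a warning.
    """
    W = frames.shape[1]
    margin = max(1, W // 4)
    resets: list[int] = []
    # Painted extent of frame 0 (against a black screen) seeds prev_end so
    # that a full-width repaint on frame 1 is recognized as a wrap.
    first_cols = np.flatnonzero(np.abs(frames.frames[0].astype(int)).sum(axis=0) > 0)
    prev_end = int(first_cols[-1]) + 1 if first_cols.size else 0
    any_change = False
    for i in range(1, len(frames)):
        band = _diff_band(frames.frames[i - 1], frames.frames[i])
        if band is None:
            continue
        any_change = True
        start, end = band
        if start < margin and prev_end > W - margin and end <= prev_end:
            resets.append(i)
        prev_end = end
    if not any_change:
        warnings.warn("video frames are all identical; no sweeps detected",
                      stacklevel=2)
    return resets


def stitch_frames(frames: FrameSequence, resets: list[int]) -> np.ndarray:
    """Concatenate the fully painted frame of every completed sweep.

    The frame immediately before each reset holds the completed sweep; they
    are concatenated left to right in time order.  Data painted after the
    last reset belongs to an unfinished sweep and is discarded; with no
    resets at all the last frame (a single, fully painted sweep) is
    returned unchanged.
    """
    if sorted(set(resets)) != list(resets):
        raise ValidationError("reset indices must be sorted and unique")
    if resets and (resets[0] < 1 or resets[-1] >= len(frames)):
        raise ValidationError("reset indices out of range")
    if not resets:
        return frames.frames[-1].copy()
    segments = [frames.frames[r - 1] for r in resets]
    return np.concatenate(segments, axis=1)


def crop_regions(image: np.ndarray,
                 layout: RegionLayout) -> tuple[np.ndarray, np.ndarray]:
    """Split a stitched strip into its Doppler and ECG row bands."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("expected a 2-D strip image")
    h = image.shape[0]
    for name, (a, b) in (("doppler_rows", layout.doppler_rows),
                         ("ecg_rows", layout.ecg_rows)):
        if b > h:
            raise ValidationError(f"{name} {a, b} outside image of height {h}")
    d0, d1 = layout.doppler_rows
    e0, e1 = layout.ecg_rows
    return image[d0:d1].copy(), image[e0:e1].copy()
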