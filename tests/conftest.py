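import numpy as np
import pytest

import coroflow as cf


@pytest.fixture(scope="session")
def baseline_strip():
    """One standard baseline recording with its ground truth."""
    spec = cf.default_strip_spec("baseline", seed=1)
    strip, truth = cf.generate_strip(spec)
    return spec, strip, truth


@pytest.fixture(scope="session")
def baseline_analysis(baseline_strip):
    _, strip, _ = baseline_strip
    return cf.analyze_strip(strip)


@pytest.fixture(scope="session")
def hyperemia_strip():
    spec = cf.default_strip_spec("hyperemia", seed=2)
    strip, truth = cf.generate_strip(spec)
    return spec, strip, truth


def simulate_sweep_cursor(strip_width: int, frame_width: int, sweep: int):
    """Independent cursor-arithmetic oracle for the scrolling display.

    Returns (n_frames, reset_frame_indices, total_stitched_width) by
    stepping the cursor exactly as a console would: paint ``sweep``
    columns per frame, wrap at the frame's right edge, and emit one
    trailing wrap frame after the last completed sweep (none if the strip
    ends mid-sweep).
    """
    n_full, leftover = divmod(strip_width, frame_width)
    frames = 0
    resets = []
    for _ in range(n_full):
        if frames:
            resets.append(frames)
        c = sweep
        while True:
            frames += 1
            if min(c, frame_width) == frame_width:
                break
            c += sweep
    if leftover:
        resets.append(frames)
        c = sweep
        while True:
            frames += 1
            if min(c, leftover) == leftover:
                break
            c += sweep
    else:
        resets.append(frames)
        frames += 1
    return frames, resets, n_full * frame_width
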