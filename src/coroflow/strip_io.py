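"""The DopplerStrip container and its on-disk form (PNG + JSON sidecar)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .envelope_extraction import Calibration, ValidationError
from .video_ingest import RegionLayout, crop_regions


@dataclass
class DopplerStrip:
    """A continuous grayscale strip with its calibration and row layout.

    ``image`` stacks the Doppler band above the ECG band; ``layout`` locates
    both, and ``calibration`` maps Doppler-band pixels to mm/s and ms.
    """

    image: np.ndarray
    layout: RegionLayout
    calibration: Calibration

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValidationError("strip image must be 2-D grayscale")

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def doppler(self) -> np.ndarray:
        return crop_regions(self.image, self.layout)[0]

    @property
    def ecg(self) -> np.ndarray:
        return crop_regions(self.image, self.layout)[1]


def write_strip(strip: DopplerStrip, png_path: str | Path) -> None:
    """Write the strip as 8-bit PNG plus a ``.json`` calibration sidecar."""
    import imageio.v3 as iio

    png_path = Path(png_path)
    iio.imwrite(png_path, strip.image.astype(np.uint8))
    cal, lay = strip.calibration, strip.layout
    sidecar = {
        "scale_max_v": cal.scale_max_v,
        "ms_per_px": cal.ms_per_px,
        "baseline_row": cal.baseline_row,
        "rows_above_baseline": cal.rows_above_baseline,
        "doppler_rows": list(lay.doppler_rows),
        "ecg_rows": list(lay.ecg_rows),
        "scale_col": lay.scale_col,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_strip(png_path: str | Path) -> DopplerStrip:
    """Read a strip PNG and its JSON sidecar back into a DopplerStrip."""
    import imageio.v3 as iio

    png_path = Path(png_path)
    image = np.asarray(iio.imread(png_path))
    if image.ndim == 3:
        image = image[..., :3].mean(axis=2).astype(np.uint8)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    cal = Calibration(scale_max_v=meta["scale_max_v"],
                      ms_per_px=meta["ms_per_px"],
                      baseline_row=meta["baseline_row"],
                      rows_above_baseline=meta.get("rows_above_baseline", 0))
    lay = RegionLayout(doppler_rows=tuple(meta["doppler_rows"]),
                       ecg_rows=tuple(meta["ecg_rows"]),
                       scale_col=meta.get("scale_col"))
    return DopplerStrip(image=image, layout=lay, calibration=cal)
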