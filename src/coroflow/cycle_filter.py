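"""Rejection of unrepresentative cardiac cycles and summary statistics.

Cycles in which the coronary artery transiently drifted out of the sample
volume show abnormally low peak velocity and VTI.  They are removed by
comparing each cycle's peak velocity and VTI against the data set's
central value: a cycle falls if either value is below a configured
fraction of the center.  The comparison is re-run on the surviving set
until a fixed point (the center is recomputed without the outliers it
just removed), and every rejection records its reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycle_metrics import CycleMetrics
from .envelope_extraction import ValidationError


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the unrepresentative-cycle rule.

    A cycle is rejected when ``peak_velocity < pv_frac * center(PV)`` or
    ``vti < vti_frac * center(VTI)`` over the currently kept cycles.  The
    median is the default center: it resists the very outliers being
    removed.  ``max_iterations=1`` gives the single-pass variant.
    """

    pv_frac: float = 0.6
    vti_frac: float = 0.6
    center: str = "median"
    max_iterations: int = 3

    def __post_init__(self) -> None:
        for name in ("pv_frac", "vti_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.center not in ("mean", "median"):
            raise ValidationError("center must be 'mean' or 'median'")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class Rejection:
    """Index of a rejected cycle and why it fell."""

    index: int
    reason: str


@dataclass
class SummaryTable:
    """Mean/SD of every metric over the kept cycles.

    ``table`` is indexed by metric name with columns ``mean``, ``sd`` and
    ``n`` (metrics undefined in some cycles are excluded pairwise, so ``n``
    can differ per metric; SD uses the n-1 denominator).
    """

    table: pd.DataFrame
    n_kept: int
    n_rejected: int


def _center(values: np.ndarray, how: str) -> float:
    return float(np.median(values) if how == "median" else np.mean(values))


def flag_unrepresentative(metrics: list[CycleMetrics],
                          cfg: FilterConfig = FilterConfig(),
                          ) -> tuple[list[int], list[Rejection]]:
    """Partition cycle indices into kept and rejected sets.

    Iterates to a fixed point (or ``max_iterations``): the rejected set can
    only grow across iterations, and the same input with the same config
    always yields the same partition.
    """
    if len(metrics) < 3:
        raise ValidationError("need >= 3 cycles to judge representativeness")
    kept = list(range(len(metrics)))
    rejections: list[Rejection] = []
    for _ in range(cfg.max_iterations):
        pv = np.array([metrics[i].peak_velocity for i in kept])
        vti = np.array([metrics[i].vti for i in kept])
        ok = np.isfinite(pv) & np.isfinite(vti)
        if not ok.any():
            raise ValidationError("no cycle has defined peak velocity and VTI")
        c_pv = _center(pv[ok], cfg.center)
        c_vti = _center(vti[ok], cfg.center)
        new_kept, dropped = [], []
        for i in kept:
            m = metrics[i]
            reasons = []
            if math.isfinite(m.peak_velocity) and \
                    m.peak_velocity < cfg.pv_frac * c_pv:
                reasons.append(
                    f"peak_velocity {m.peak_velocity:.1f} < "
                    f"{cfg.pv_frac:g} x {cfg.center} {c_pv:.1f}")
            if math.isfinite(m.vti) and m.vti < cfg.vti_frac * c_vti:
                reasons.append(f"vti {m.vti:.2f} < "
                               f"{cfg.vti_frac:g} x {cfg.center} {c_vti:.2f}")
            if reasons:
                dropped.append(Rejection(index=i, reason="; ".join(reasons)))
            else:
                new_kept.append(i)
        rejections.extend(dropped)
        if not new_kept:
            raise ValidationError(
                "all cycles rejected as unrepresentative; recording unusable")
        if not dropped:
            break
        kept = new_kept
    rejections.sort(key=lambda r: r.index)
    return kept, rejections


def summarize(kept: list[CycleMetrics]) -> SummaryTable:
    """Per-metric mean and sample SD (n-1) over the kept cycles.

    Undefined (NaN) entries are excluded metric by metric; the per-metric
    count of defined values is reported alongside.
    """
    if not kept:
        raise ValidationError("cannot summarize an empty set of cycles")
    rows = {}
    for name in CycleMetrics.field_names():
        vals = np.array([getattr(m, name) for m in kept], dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mean = float(vals.mean()) if n else math.nan
        sd = float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else math.nan)
        rows[name] = {"mean": mean, "sd": sd, "n": n}
    table = pd.DataFrame(rows).T[["mean", "sd", "n"]]
    table["n"] = table["n"].astype(int)
    return SummaryTable(table=table, n_kept=len(kept), n_rejected=0)


def filter_and_summarize(metrics: list[CycleMetrics],
                         cfg: FilterConfig = FilterConfig(),
                         ) -> tuple[list[int], list[Rejection], SummaryTable]:
    """Apply the rejection rule and summarize the survivors."""
    kept_idx, rejections = flag_unrepresentative(metrics, cfg)
    summary = summarize([metrics[i] for i in kept_idx])
    summary.n_rejected = len(rejections)
    return kept_idx, rejections, summary
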