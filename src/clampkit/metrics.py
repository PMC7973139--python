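"""Whole-cell current metrics from annotated traces and cohort statistics.

Plateau values are means over the final fraction of a segment (default
20%); maneuver-difference metrics are reported as non-negative magnitudes
(inward currents are negative in the raw traces).  Negative difference
estimates are clipped to 0 with a :class:`MetricWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import CohortTable, Condition, Segment, SegmentAnnotation, Trace

__all__ = [
    "MetricWindows",
    "MetricWarning",
    "measure_delta_ami",
    "measure_divalent_removal",
    "relative_inhibition",
    "fold_stimulation",
    "batch_normalize",
    "summarize_groups",
]


class MetricWarning(UserWarning):
    """Raised (as a warning) when a metric is clipped or suspect."""


@dataclass(frozen=True)
class MetricWindows:
    """Averaging windows for plateau metrics.

    ``plateau_fraction``: final fraction of each segment averaged.
    ``guard_s``: seconds excluded at the start of a segment following a
    divalent-free interval (post-readdition transient).
    """

    plateau_fraction: float = 0.2
    guard_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must be in (0, 1]")


def plateau_mean(trace: Trace, seg: Segment, windows: MetricWindows) -> float:
    """Mean current over the final ``plateau_fraction`` of a segment."""
    start = seg.end - (seg.end - seg.start) * windows.plateau_fraction
    values = trace.window(start, seg.end)
    if values.size == 0:
        raise ValueError(f"empty plateau window in segment at t={seg.start}")
    return float(values.mean())


def measure_delta_ami(
    trace: Trace,
    ann: SegmentAnnotation,
    windows: MetricWindows = MetricWindows(),
) -> float:
    """Amiloride-sensitive current magnitude.

    |mean(washout plateau) - mean(amiloride plateau)| for the first
    amiloride/washout pair of adjacent segments.  If the washout plateau
    is *less* inward than the blocked baseline the estimate is clipped to
    0 with a warning.
    """
    ami_segs = ann.by_condition(Condition.AMILORIDE)
    wash_segs = ann.by_condition(Condition.WASHOUT)
    if not ami_segs or not wash_segs:
        raise ValueError("annotation needs >=1 amiloride and >=1 washout segment")
    # prefer an adjacent (amiloride, washout) pair
    pair = None
    for w in wash_segs:
        for a in ami_segs:
            if abs(a.end - w.start) < 1e-9 or abs(w.end - a.start) < 1e-9:
                pair = (a, w)
                break
        if pair:
            break
    if pair is None:
        pair = (ami_segs[0], wash_segs[0])
    ami, wash = pair
    delta = plateau_mean(trace, ami, windows) - plateau_mean(trace, wash, windows)
    if delta < 0:
        warnings.warn(
            "washout plateau less inward than amiloride baseline; clipped to 0",
            MetricWarning,
        )
        return 0.0
    return float(delta)


def measure_divalent_removal(
    trace: Trace,
    ann: SegmentAnnotation,
    windows: MetricWindows = MetricWindows(),
) -> float:
    """Divalent-removal current magnitude.

    |inward extremum during the divalent-free window - mean(preceding
    plateau)|.  The post-readdition transient lies outside the
    divalent-free window and is therefore excluded.
    """
    div_segs = ann.by_condition(Condition.DIVALENT_FREE)
    if not div_segs:
        raise ValueError("annotation has no divalent_free segment")
    div = div_segs[0]
    base = ann.preceding(div)
    if base is None:
        raise ValueError("divalent_free segment has no preceding baseline")
    baseline = plateau_mean(trace, base, windows)
    window = trace.window(div.start, div.end)
    if window.size == 0:
        raise ValueError("empty divalent_free window")
    extremum = float(window.min())  # most inward
    delta = baseline - extremum
    if delta < 0:
        warnings.warn("no inward response to divalent removal; clipped to 0", MetricWarning)
        return 0.0
    return float(delta)


def relative_inhibition(delta_i: float, control_mean: float) -> float:
    """Relative inhibitory effect in percent, positive for inhibition.

    Returns -(delta_i / control_mean - 1) * 100.  The underlying ratio
    formula yields negative values for inhibition; the sign is flipped
    here once so that reported percentages are positive-for-inhibition.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return -(delta_i / control_mean - 1.0) * 100.0


def fold_stimulation(before: float, after: float) -> float:
    """Fold change after a stimulating maneuver (after / before)."""
    if before <= 0:
        raise ValueError("pre-stimulation current must be positive")
    return after / before


def batch_normalize(
    cohort: CohortTable,
    control_group: str,
    column: str = "delta_i_ami",
    out_column: str = "normalized",
) -> CohortTable:
    """Divide each value by the control-group mean within its own batch."""
    df = cohort.df.copy()
    control = df[df["group"] == control_group]
    batch_means = control.groupby("batch_id")[column].mean()
    missing = sorted(set(df["batch_id"]) - set(batch_means.index))
    if missing:
        raise ValueError(f"batches without control-group oocytes: {missing}")
    df[out_column] = df[column] / df["batch_id"].map(batch_means)
    return CohortTable(df)


def summarize_groups(cohort: CohortTable, column: str = "delta_i_ami") -> pd.DataFrame:
    """Per-group mean, SEM (sd/sqrt(n); NaN for n=1), n oocytes, N batches."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    def _summary(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        sem = g[column].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series(
            {
                "mean": g[column].mean(),
                "sem": sem,
                "n": n,
                "N": g["batch_id"].nunique(),
            }
        )

    out = cohort.df.groupby("group", sort=False).apply(_summary, include_groups=False)
    out[["n", "N"]] = out[["n", "N"]].astype(int)
    return out
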