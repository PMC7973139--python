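"""Retrieval-rate estimation from two-application covalent-modification
timecourses, with insertion correction, plus the cohort-level
proportional regression.

The calculus inverts the forward model in :mod:`clampkit.trafficking`:
a first reagent application locks surface channels fully open; the
subsequent current decline reflects retrieval of modified channels
partially compensated by insertion of fresh low-open-probability
channels, whose contribution is estimated from the response to a second
application at the final time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "MtsetSeries",
    "RetrievalEstimate",
    "estimate_po_initial",
    "insertion_correction",
    "retrieval_current",
    "corrected_remaining_fraction",
    "normalized_decay",
    "proportional_fit",
]


@dataclass
class MtsetSeries:
    """Per-oocyte amiloride-sensitive current timecourse around two
    reagent applications.

    ``di_before``: current before the first application.
    ``di_t``: minutes after the first application -> current; must
    include time 0 (plateau right after the first application) and the
    final time point (default protocol: 70 min) at which the second
    application is made.
    ``di_second_mtset``: current increase upon the second application.
    """

    di_before: float
    di_t: Dict[float, float]
    di_second_mtset: float
    oocyte_id: str = ""

    def __post_init__(self) -> None:
        if 0.0 not in self.di_t:
            raise ValueError("di_t must include time 0")
        if len(self.di_t) < 2:
            raise ValueError("di_t must include a final time point after 0")
        if any(v < 0 for v in self.di_t.values()) or self.di_before < 0 or (
            self.di_second_mtset < 0
        ):
            raise ValueError("currents must be non-negative magnitudes")
        self.di_t = dict(sorted(self.di_t.items()))
        if self.di_before > self.di_t[0.0]:
            warnings.warn(
                "di_before exceeds di_t[0]; modification should stimulate "
                "(noisy series?)",
                UserWarning,
            )

    @property
    def t_final(self) -> float:
        return max(self.di_t)


@dataclass
class RetrievalEstimate:
    po_initial: float
    di_insertion: float
    di_retrieval: float
    normalized_retrieval: float
    remaining_fraction_corrected: float
    flags: List[str] = field(default_factory=list)


def estimate_po_initial(series: MtsetSeries) -> float:
    """Baseline open probability: di_before / di_t[0], clipped to [0, 1]."""
    di0 = series.di_t[0.0]
    if di0 <= 0:
        raise ValueError("di_t[0] must be positive")
    po = series.di_before / di0
    if po > 1:
        warnings.warn("po_initial > 1; clipped", UserWarning)
        return 1.0
    return po


def insertion_correction(series: MtsetSeries) -> float:
    """Current carried at the final time by channels inserted after the
    first application: di_second_mtset * po / (1 - po)."""
    po = estimate_po_initial(series)
    if po >= 1:
        raise ValueError("insertion correction undefined for po_initial = 1")
    return series.di_second_mtset * po / (1.0 - po)


def retrieval_current(series: MtsetSeries) -> RetrievalEstimate:
    """Insertion-corrected current decline attributable to retrieval.

    di_retrieval = di_t[0] - (di_t[final] - di_insertion).
    """
    flags: List[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        po = estimate_po_initial(series)
        di_ins = insertion_correction(series)
        flags.extend(str(w.message) for w in caught)
    di0 = series.di_t[0.0]
    di_final = series.di_t[series.t_final]
    di_ret = di0 - (di_final - di_ins)
    if di_ret > di0:
        flags.append("di_retrieval exceeds di_t[0]; inconsistent with steady state")
    normalized = di_ret / di0
    return RetrievalEstimate(
        po_initial=po,
        di_insertion=di_ins,
        di_retrieval=di_ret,
        normalized_retrieval=normalized,
        remaining_fraction_corrected=1.0 - normalized,
        flags=flags,
    )


def corrected_remaining_fraction(raw_remaining: float, po_initial: float) -> float:
    """Closed-form steady-state identity for the insertion correction.

    Under exact steady state (second application restores the time-0
    current), the corrected remaining fraction equals
    (raw_remaining - po_initial) / (1 - po_initial).
    """
    if po_initial >= 1:
        raise ValueError("undefined for po_initial >= 1")
    if raw_remaining < po_initial:
        raise ValueError(
            "raw remaining fraction below po_initial is inconsistent with steady state"
        )
    return (raw_remaining - po_initial) / (1.0 - po_initial)


def normalized_decay(series: MtsetSeries) -> Dict[float, float]:
    """Currents normalized to the value at time 0."""
    di0 = series.di_t[0.0]
    if di0 <= 0:
        raise ValueError("di_t[0] must be positive")
    return {t: v / di0 for t, v in series.di_t.items()}


def proportional_fit(x, y) -> Tuple[float, float]:
    """Least-squares fit of y = k * x through the origin.

    Returns (k, SE(k)) with the SE computed from residual variance:
    k = sum(xy)/sum(x^2), SE = sqrt(sum(r^2) / ((n-1) * sum(x^2))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate x (all zero)")
    k = float(np.dot(x, y)) / sxx
    resid = y - k * x
    se = float(np.sqrt(np.dot(resid, resid) / ((x.size - 1) * sxx)))
    return k, se


def linear_fit(x, y) -> Tuple[float, float]:
    """Free-intercept least-squares line (diagnostic alternative).

    Returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
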