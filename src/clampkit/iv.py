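"""I/V relations from voltage-step protocols: reversal potentials,
background subtraction, and permeability ratios."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .core import PhysConstants, Trace

__all__ = [
    "StepProtocol",
    "IVCurve",
    "build_iv",
    "estimate_reversal",
    "subtract_background",
    "permeability_ratio",
]


@dataclass(frozen=True)
class StepProtocol:
    """Consecutive voltage steps; default nine 2 s steps in 20 mV
    increments from -120 mV, analyzed over the final 100 ms."""

    start: float = -120.0
    increment: float = 20.0
    n_steps: int = 9
    step_duration: float = 2.0
    analysis_window: float = 0.1

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not 0 < self.analysis_window <= self.step_duration:
            raise ValueError("analysis_window must be in (0, step_duration]")

    @property
    def potentials(self) -> np.ndarray:
        return self.start + self.increment * np.arange(self.n_steps)


@dataclass
class IVCurve:
    potentials: np.ndarray
    currents: np.ndarray
    sem: Optional[np.ndarray] = None
    n: int = 1

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape:
            raise ValueError("potentials and currents must have equal length")
        if np.any(np.diff(self.potentials) <= 0):
            raise ValueError("potentials must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.potentials.shape:
                raise ValueError("sem length mismatch")


def build_iv(step_traces: Sequence[Trace], protocol: StepProtocol) -> IVCurve:
    """Average the final ``analysis_window`` of each step trace."""
    if len(step_traces) != protocol.n_steps:
        raise ValueError(
            f"expected {protocol.n_steps} step traces, got {len(step_traces)}"
        )
    currents = []
    for trace in step_traces:
        if trace.duration < protocol.step_duration - trace.dt:
            raise ValueError("step trace shorter than protocol step duration")
        tail = trace.window(
            protocol.step_duration - protocol.analysis_window, protocol.step_duration
        )
        currents.append(float(tail.mean()))
    return IVCurve(protocol.potentials, np.array(currents))


def estimate_reversal(iv: IVCurve, method: str = "interpolate") -> float:
    """Zero-current potential (mV).

    ``method="interpolate"``: linear interpolation between the bracketing
    pair of points around zero current (the sign change nearest 0 mV if
    there are several).  ``method="local_fit"``: least-squares line
    through the 3 points nearest the interpolated crossing.
    """
    v, i = iv.potentials, iv.currents
    exact = np.flatnonzero(i == 0)
    crossings: List[float] = [float(v[k]) for k in exact]
    sign_change = np.flatnonzero(i[:-1] * i[1:] < 0)
    for k in sign_change:
        crossings.append(float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])))
    if not crossings:
        raise ValueError("reversal outside protocol range (no zero crossing)")
    erev = min(crossings, key=abs)
    if method == "interpolate":
        return erev
    if method == "local_fit":
        order = np.argsort(np.abs(v - erev))[:3]
        slope, intercept = np.polyfit(v[order], i[order], 1)
        if slope == 0:
            raise ValueError("degenerate local fit (zero slope)")
        return float(-intercept / slope)
    raise ValueError(f"unknown method {method!r}")


def subtract_background(test: IVCurve, control_mean: IVCurve) -> IVCurve:
    """Pointwise test - control difference on identical potential grids.

    The control mean is treated as fixed: the result carries the test
    curve's SEM only.
    """
    if not np.allclose(test.potentials, control_mean.potentials):
        raise ValueError("potential grids differ")
    return IVCurve(
        test.potentials,
        test.currents - control_mean.currents,
        sem=None if test.sem is None else test.sem.copy(),
        n=test.n,
    )


def permeability_ratio(
    delta_erev: float, constants: PhysConstants = PhysConstants()
) -> float:
    """Relative permeability of a substituting cation, P_X/P_Na.

    Returns exp(delta_erev / (RT/F)) where ``delta_erev`` is the
    reversal-potential shift (mV) upon full substitution of Na by the
    test cation.
    """
    return math.exp(delta_erev / constants.rt_over_f)
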