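"""Forward kinetic model of surface-channel trafficking under covalent
open-probability locking.

Two pools of channels at the cell surface: a covalently modified pool
(open probability ``po_modified``, default 1) and an unmodified pool
(``po_baseline``).  Both are retrieved with first-order rate constant
``lambda_ret`` (per minute); unmodified channels are inserted at constant
flux ``j_ins`` (channels/min).  A modification event instantaneously
converts the entire unmodified pool to the modified pool.

Dynamics between events are solved in closed form (no ODE stepping):

    dN_mod/dt   = -lambda * N_mod
    dN_unmod/dt = J - lambda * N_unmod
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

__all__ = [
    "TraffickingParams",
    "SurfaceState",
    "steady_state",
    "simulate",
    "predicted_delta_ami",
]


@dataclass(frozen=True)
class TraffickingParams:
    """Ground-truth kinetic parameters.

    ``unitary`` converts open-channel count to measured current
    (driving force is absorbed into it); units are whatever current unit
    the caller works in, per channel.
    """

    lambda_ret: float  # per minute, first-order retrieval
    j_ins: float  # channels per minute, insertion of unmodified channels
    n0: float  # initial surface channel count
    po_baseline: float  # open probability of unmodified channels
    po_modified: float = 1.0
    unitary: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_ret < 0 or self.j_ins < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.po_baseline <= self.po_modified <= 1:
            raise ValueError("need 0 <= po_baseline <= po_modified <= 1")
        if not self.n0 > 0:
            raise ValueError("n0 must be positive")


@dataclass(frozen=True)
class SurfaceState:
    t: float  # minutes
    n_modified: float
    n_unmodified: float

    @property
    def n_total(self) -> float:
        return self.n_modified + self.n_unmodified


def steady_state(params: TraffickingParams) -> TraffickingParams:
    """Set insertion flux to balance retrieval so total surface count is
    time-invariant: j_ins = lambda_ret * n0."""
    return replace(params, j_ins=params.lambda_ret * params.n0)


def _evolve(
    m0: float, u0: float, lam: float, j: float, delta_t: float
) -> tuple[float, float]:
    """Closed-form state advance over delta_t minutes (no events)."""
    if delta_t < 0:
        raise ValueError("cannot evolve backwards in time")
    if lam == 0:
        return m0, u0 + j * delta_t
    decay = math.exp(-lam * delta_t)
    u_inf = j / lam
    return m0 * decay, u_inf + (u0 - u_inf) * decay


def simulate(
    params: TraffickingParams,
    mtset_times: Sequence[float],
    t_grid: Sequence[float],
) -> List[SurfaceState]:
    """Simulate the two-pool model on ``t_grid`` (minutes).

    All channels start unmodified.  At each time in ``mtset_times`` the
    unmodified pool is instantaneously converted; a grid point that
    coincides with an event reports the post-event state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be non-decreasing")
    events = sorted(mtset_times)

    m, u = 0.0, float(params.n0)
    t0 = float(t_grid[0]) if t_grid.size else 0.0
    cursor = min([t0] + events)  # simulation clock starts at/before first output
    out: List[SurfaceState] = []
    ev_idx = 0

    def advance_to(t: float) -> None:
        nonlocal m, u, cursor, ev_idx
        while ev_idx < len(events) and events[ev_idx] <= t + 1e-12:
            te = events[ev_idx]
            m, u = _evolve(m, u, params.lambda_ret, params.j_ins, te - cursor)
            m, u = m + u, 0.0  # instantaneous complete modification
            cursor = te
            ev_idx += 1
        m, u = _evolve(m, u, params.lambda_ret, params.j_ins, t - cursor)
        cursor = t

    for t in t_grid:
        advance_to(float(t))
        out.append(SurfaceState(float(t), m, u))
    return out


def predicted_delta_ami(state: SurfaceState, params: TraffickingParams) -> float:
    """Amiloride-sensitive current predicted from a surface state."""
    return params.unitary * (
        state.n_modified * params.po_modified
        + state.n_unmodified * params.po_baseline
    )
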