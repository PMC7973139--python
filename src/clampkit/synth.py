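"""Synthetic-data generators with known ground truth.

Emulates the statistical structure of oocyte voltage-clamp cohorts:
lognormal per-oocyte expression heterogeneity, multiplicative lognormal
batch factors, amiloride block/washout relaxations, divalent-removal
hemichannel currents, modification-protocol timecourses driven by the
forward trafficking model, ohmic step-protocol recordings, and
stochastic two-state multi-channel gating.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import trafficking
from .core import (
    CohortTable,
    Condition,
    OocyteMeasurement,
    Segment,
    SegmentAnnotation,
    Trace,
)
from .iv import StepProtocol
from .retrieval import MtsetSeries
from .trafficking import TraffickingParams

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "GatingSpec",
    "CohortBundle",
    "generate_cohort",
    "simulate_mtset_timecourse",
    "simulate_mtset_cohort",
    "simulate_step_protocol",
    "simulate_single_channel",
]

#: Whole-cell protocol layout (seconds): block -> washout -> block ->
#: divalent removal (still blocked) -> readdition baseline.
_PROTOCOL = (
    (0.0, 30.0, Condition.AMILORIDE, "ND96"),
    (30.0, 70.0, Condition.WASHOUT, "ND96"),
    (70.0, 100.0, Condition.AMILORIDE, "ND96"),
    (100.0, 160.0, Condition.DIVALENT_FREE, "divalent-free"),
    (160.0, 180.0, Condition.BASELINE, "ND96"),
)
_TRACE_DT = 0.05  # s


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of a synthetic cohort.

    ``mean_di_ami_uA``: group-mean amiloride-sensitive current (uA).
    ``inhibition``: fractional reduction of that mean relative to an
    uninhibited reference (0 = control-like expression).
    ``camg_scale_uA``: mean divalent-removal hemichannel current (uA);
    0 for groups without hemichannel expression.
    """

    name: str
    mean_di_ami_uA: float
    inhibition: float = 0.0
    camg_scale_uA: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.inhibition <= 1:
            raise ValueError("inhibition must be in [0, 1]")
        if self.mean_di_ami_uA < 0 or self.camg_scale_uA < 0:
            raise ValueError("current scales must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    n_oocytes: int  # per group
    n_batches: int
    groups: Tuple[GroupSpec, ...]
    expression_cv: float = 0.5  # lognormal per-oocyte CV
    batch_cv: float = 0.2  # lognormal batch-factor CV
    noise_sd: float = 5.0  # nA, additive per-sample trace noise
    relax_tau: float = 2.0  # s, solution-exchange relaxation
    divalent_spike: bool = True  # post-readdition transient artifact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oocytes < 1 or self.n_batches < 1:
            raise ValueError("counts must be >= 1")
        if self.expression_cv < 0 or self.batch_cv < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be >= 0")
        if not self.groups:
            raise ValueError("need at least one group")


@dataclass(frozen=True)
class GatingSpec:
    """Two-state gating parameters for a simulated patch.

    Open probability must be consistent with the dwell means:
    p_open = mean_open / (mean_open + mean_closed).
    """

    n_channels: int
    p_open: float
    unitary_current: float  # pA, magnitude; openings are inward
    mean_open_ms: float
    mean_closed_ms: float
    noise_sd: float = 0.0  # pA
    filter_hz: Optional[float] = 250.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0 <= self.p_open <= 1:
            raise ValueError("p_open must be in [0, 1]")
        if self.mean_open_ms <= 0 or self.mean_closed_ms <= 0:
            raise ValueError("dwell means must be positive")
        implied = self.mean_open_ms / (self.mean_open_ms + self.mean_closed_ms)
        if abs(implied - self.p_open) > 1e-9:
            raise ValueError(
                f"p_open={self.p_open} inconsistent with dwell means "
                f"(implied {implied:.6f})"
            )

    @classmethod
    def from_po(
        cls,
        n_channels: int,
        p_open: float,
        unitary_current: float,
        mean_open_ms: float = 200.0,
        noise_sd: float = 0.0,
        filter_hz: Optional[float] = 250.0,
    ) -> "GatingSpec":
        if not 0 < p_open < 1:
            raise ValueError("from_po requires 0 < p_open < 1")
        mean_closed = mean_open_ms * (1 - p_open) / p_open
        return cls(
            n_channels,
            p_open,
            unitary_current,
            mean_open_ms,
            mean_closed,
            noise_sd,
            filter_hz,
        )


@dataclass
class CohortBundle:
    """Ground truth plus per-oocyte annotated traces."""

    truth: CohortTable  # delta columns in nA (true values)
    traces: Dict[str, Tuple[Trace, SegmentAnnotation]]


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def _relaxation(t_rel: np.ndarray, tau: float) -> np.ndarray:
    """exp(-t/tau), snapped to exactly 0 beyond 10 tau so that plateau
    windows are exact on noiseless traces."""
    if tau <= 0:
        return np.zeros_like(t_rel)
    out = np.exp(-t_rel / tau)
    out[t_rel >= 10.0 * tau] = 0.0
    return out


def _render_trace(
    di_ami_nA: float,
    di_camg_nA: float,
    leak_nA: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> Tuple[Trace, SegmentAnnotation]:
    """Whole-cell trace (nA, inward negative) for one oocyte."""
    n = int(round(_PROTOCOL[-1][1] / _TRACE_DT))
    t = np.arange(n) * _TRACE_DT
    # target plateau per segment
    levels = {
        Condition.AMILORIDE: leak_nA,
        Condition.WASHOUT: leak_nA - di_ami_nA,
        Condition.DIVALENT_FREE: leak_nA - di_camg_nA,
        Condition.BASELINE: leak_nA,
    }
    current = np.empty(n)
    prev_level = leak_nA
    for start, end, cond, _sol in _PROTOCOL:
        i0, i1 = int(round(start / _TRACE_DT)), int(round(end / _TRACE_DT))
        target = levels[cond]
        relax = _relaxation(t[i0:i1] - start, spec.relax_tau)
        current[i0:i1] = target + (prev_level - target) * relax
        prev_level = target
    if spec.divalent_spike and di_camg_nA > 0:
        # transient inward artifact right after divalent readdition;
        # lies outside the divalent-free measurement window
        start, end = _PROTOCOL[-1][0], _PROTOCOL[-1][0] + 3.0
        i0, i1 = int(round(start / _TRACE_DT)), int(round(end / _TRACE_DT))
        current[i0:i1] += -0.5 * di_camg_nA * np.exp(-(t[i0:i1] - start) / 0.5)
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=n)
    ann = SegmentAnnotation([Segment(*p[:2], p[2], p[3]) for p in _PROTOCOL])
    return Trace(_TRACE_DT, current, units="nA"), ann


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate a cohort of annotated whole-cell traces with ground truth.

    Each oocyte's true currents are
    ``mean * (1 - inhibition) * expression_factor * batch_factor`` with
    unit-mean lognormal factors; traces follow the block/washout/block/
    divalent-removal protocol.
    """
    rng = np.random.default_rng(spec.seed)
    batch_factors = _lognormal_factors(rng, spec.n_batches, spec.batch_cv)
    rows: List[OocyteMeasurement] = []
    traces: Dict[str, Tuple[Trace, SegmentAnnotation]] = {}
    for group in spec.groups:
        expr = _lognormal_factors(rng, spec.n_oocytes, spec.expression_cv)
        expr_camg = _lognormal_factors(rng, spec.n_oocytes, spec.expression_cv)
        for j in range(spec.n_oocytes):
            batch = j % spec.n_batches
            bf = batch_factors[batch]
            di_ami = 1000.0 * group.mean_di_ami_uA * (1 - group.inhibition) * expr[j] * bf
            di_camg = 1000.0 * group.camg_scale_uA * expr_camg[j] * bf
            oid = f"{group.name}-b{batch}-{j:03d}"
            rows.append(
                OocyteMeasurement(oid, f"batch{batch}", group.name, di_ami, di_camg)
            )
            traces[oid] = _render_trace(di_ami, di_camg, leak_nA=-50.0, spec=spec, rng=rng)
    return CohortBundle(CohortTable(rows), traces)


def simulate_mtset_timecourse(
    params: TraffickingParams,
    sample_times: Sequence[float] = tuple(range(0, 80, 10)),
    noise_sd: float = 0.0,
    seed: int = 0,
    oocyte_id: str = "",
    rng: Optional[np.random.Generator] = None,
) -> MtsetSeries:
    """Timecourse of the two-application modification protocol.

    The first application is at t=0 min; the second at the final sample
    time.  ``noise_sd`` is the *relative* (fractional) Gaussian
    measurement noise applied multiplicatively to every reported
    current.  Returns the per-oocyte series consumed by
    :mod:`clampkit.retrieval`.
    """
    times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if times[0] != 0.0:
        raise ValueError("sample_times must start at 0 (first application)")
    if rng is None:
        rng = np.random.default_rng(seed)
    t_final = float(times[-1])

    # pre-application current: all channels unmodified at baseline Po
    di_before = params.unitary * params.n0 * params.po_baseline
    states = trafficking.simulate(params, mtset_times=[0.0], t_grid=times)
    di_t = {s.t: trafficking.predicted_delta_ami(s, params) for s in states}
    final = states[-1]
    di_second = (
        params.unitary
        * final.n_unmodified
        * (params.po_modified - params.po_baseline)
    )

    def _noisy(v: float) -> float:
        if noise_sd == 0:
            return v
        return max(v * (1.0 + rng.normal(0.0, noise_sd)), 0.0)

    series = MtsetSeries(
        di_before=_noisy(di_before),
        di_t={t: _noisy(v) for t, v in di_t.items()},
        di_second_mtset=_noisy(di_second),
        oocyte_id=oocyte_id,
    )
    return series


def simulate_mtset_cohort(
    params: TraffickingParams,
    n_oocytes: int,
    expression_cv: float = 0.5,
    noise_sd: float = 0.02,
    seed: int = 0,
    sample_times: Sequence[float] = tuple(range(0, 80, 10)),
) -> List[MtsetSeries]:
    """Cohort of modification timecourses with lognormal expression.

    Expression heterogeneity scales the surface channel count; kinetic
    parameters are shared (homogeneous true retrieval fraction).
    """
    rng = np.random.default_rng(seed)
    scale = _lognormal_factors(rng, n_oocytes, expression_cv)
    out = []
    for j in range(n_oocytes):
        p = trafficking.steady_state(
            TraffickingParams(
                lambda_ret=params.lambda_ret,
                j_ins=params.j_ins,
                n0=params.n0 * scale[j],
                po_baseline=params.po_baseline,
                po_modified=params.po_modified,
                unitary=params.unitary,
            )
        )
        out.append(
            simulate_mtset_timecourse(
                p, sample_times, noise_sd, oocyte_id=f"oo{j:03d}", rng=rng
            )
        )
    return out


def simulate_step_protocol(
    conductance_uS: float,
    true_erev: float,
    protocol: StepProtocol = StepProtocol(),
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.01,
) -> List[Trace]:
    """Ohmic step-protocol recording: one steady trace per step.

    Per-step current (nA) = conductance (uS) * (V - true_erev) (mV),
    plus additive Gaussian noise.
    """
    if conductance_uS < 0:
        raise ValueError("conductance must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(protocol.step_duration / dt))
    traces = []
    for v in protocol.potentials:
        level = conductance_uS * (v - true_erev)
        current = np.full(n, level)
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, size=n)
        traces.append(Trace(dt, current, units="nA", label=f"{v:+.0f}mV"))
    return traces


def _rasterize_dwells(
    rng: np.random.Generator,
    n_samples: int,
    dt_ms: float,
    p_open: float,
    mean_open_ms: float,
    mean_closed_ms: float,
) -> np.ndarray:
    """Boolean open/closed sample train from exponential dwell times."""
    total_ms = n_samples * dt_ms
    # start state from the stationary distribution
    state = bool(rng.random() < p_open)
    edges_ms = [0.0]
    states = [state]
    t = 0.0
    while t < total_ms:
        mean = mean_open_ms if state else mean_closed_ms
        t += rng.exponential(mean)
        edges_ms.append(t)
        state = not state
        states.append(state)
    # sample membership: dwell index at each sample midpoint
    sample_t = (np.arange(n_samples) + 0.5) * dt_ms
    idx = np.searchsorted(np.asarray(edges_ms), sample_t, side="right") - 1
    open_flags = np.asarray(states, dtype=bool)[idx]
    return open_flags


def simulate_single_channel(
    spec: GatingSpec,
    duration: float = 60.0,
    dt: float = 2e-4,
    amiloride_tail: float = 10.0,
    seed: int = 0,
) -> Tuple[Trace, SegmentAnnotation]:
    """Stochastic multi-channel patch recording (pA, openings inward).

    Independent identical two-state channels gate over
    ``duration - amiloride_tail`` seconds; the final ``amiloride_tail``
    seconds force all channels closed.  Gaussian noise of
    ``spec.noise_sd`` pA is added throughout.
    """
    if not duration > amiloride_tail >= 0:
        raise ValueError("need duration > amiloride_tail >= 0")
    dt_ms = dt * 1000.0
    if dt_ms >= min(spec.mean_open_ms, spec.mean_closed_ms):
        raise ValueError("dt >= mean dwell time: kinetics unresolvable")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration / dt))
    n_active = int(round((duration - amiloride_tail) / dt))
    open_count = np.zeros(n_total)
    for _ in range(spec.n_channels):
        flags = _rasterize_dwells(
            rng, n_active, dt_ms, spec.p_open, spec.mean_open_ms, spec.mean_closed_ms
        )
        open_count[:n_active] += flags
    current = -spec.unitary_current * open_count
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=n_total)
    segments = [Segment(0.0, duration - amiloride_tail, Condition.BASELINE, "modified-ND96")]
    if amiloride_tail > 0:
        segments.append(
            Segment(duration - amiloride_tail, duration, Condition.AMILORIDE, "modified-ND96")
        )
    return Trace(dt, current, units="pA"), SegmentAnnotation(segments)
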