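"""Shared domain types, unit conventions, and physical constants.

Sign convention: raw trace samples are signed membrane currents (inward
negative).  Condition-difference metrics (amiloride-sensitive current,
divalent-removal current) are reported as non-negative magnitudes; sign
handling is centralized in :mod:`clampkit.metrics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysConstants",
    "Solution",
    "SOLUTIONS",
    "Trace",
    "Condition",
    "Segment",
    "SegmentAnnotation",
    "OocyteMeasurement",
    "CohortTable",
    "nernst_potential",
    "effective_potential",
]

_TRACE_UNITS = ("nA", "pA")


@dataclass(frozen=True)
class PhysConstants:
    """Thermal voltage and liquid-junction correction.

    ``rt_over_f`` is RT/F in millivolts (default 25.5 mV, ~23 degC).
    ``lj_potential`` is the measured liquid-junction potential in mV,
    bath positive, subtracted from the nominal holding potential.
    """

    rt_over_f: float = 25.5
    lj_potential: float = 12.0

    def __post_init__(self) -> None:
        if not self.rt_over_f > 0:
            raise ValueError(f"rt_over_f must be > 0, got {self.rt_over_f}")


@dataclass(frozen=True)
class Solution:
    """Named bath/pipette solution with ion concentrations in mM.

    Total chloride is stored explicitly under key ``"Cl"`` (computed once
    from the salt recipe, never recomputed at use time).
    """

    name: str
    ion_mM: Mapping[str, float]

    def __post_init__(self) -> None:
        for ion, conc in self.ion_mM.items():
            if conc < 0:
                raise ValueError(f"{self.name}: negative [{ion}] = {conc}")

    def __getitem__(self, ion: str) -> float:
        return float(self.ion_mM.get(ion, 0.0))


def _sol(name: str, **ions: float) -> Solution:
    return Solution(name, dict(ions))


#: Built-in presets.  Cl totals are precomputed from the salt recipes:
#: ND96: 96 NaCl + 2 KCl + 1.8 CaCl2 + 1 MgCl2 -> 103.6 mM Cl
#: ND9 (incubation): 9 NaCl + 2 KCl + 87 NMDG-Cl + 1.8 CaCl2 + 1 MgCl2
#: NMDG-Cl bath: 95 NMDG-Cl + 1 NaCl + 2 KCl + 1.8 CaCl2 + 1 MgCl2
#: modified ND96 (single-channel bath): 96 NaCl + 4 KCl + 1 CaCl2 + 1 MgCl2
#:     -> 104 mM Cl
#: K-gluconate pipette: 90 K-gluconate + 5 NaCl (+ Mg-ATP, EGTA) -> 5 mM Cl
SOLUTIONS: Dict[str, Solution] = {
    "ND96": _sol("ND96", Na=96, K=2, Ca=1.8, Mg=1, Cl=103.6),
    "ND9": _sol("ND9", Na=9, K=2, NMDG=87, Ca=1.8, Mg=1, Cl=103.6),
    "NMDG-Cl": _sol("NMDG-Cl", NMDG=95, Na=1, K=2, Ca=1.8, Mg=1, Cl=103.6),
    "modified-ND96": _sol("modified-ND96", Na=96, K=4, Ca=1, Mg=1, Cl=104),
    "K-gluconate": _sol("K-gluconate", K=90, Na=5, Mg=2, Cl=5),
    "divalent-free": _sol("divalent-free", Na=96, K=2, Cl=98),
}


class Condition(str, Enum):
    AMILORIDE = "amiloride"
    WASHOUT = "washout"
    DIVALENT_FREE = "divalent_free"
    MTSET = "mtset"
    CHYMOTRYPSIN = "chymotrypsin"
    BASELINE = "baseline"


@dataclass
class Trace:
    """Uniformly sampled membrane-current time series."""

    dt: float
    current: np.ndarray
    units: str = "nA"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1 or self.current.size == 0:
            raise ValueError("current must be a non-empty 1-D sequence")
        if self.units not in _TRACE_UNITS:
            raise ValueError(f"units must be one of {_TRACE_UNITS}, got {self.units!r}")

    @property
    def duration(self) -> float:
        return self.current.size * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.current.size) * self.dt

    def window(self, start: float, end: float) -> np.ndarray:
        """Samples with start <= t < end."""
        i0 = int(math.ceil(start / self.dt - 1e-9))
        i1 = int(math.ceil(end / self.dt - 1e-9))
        return self.current[max(i0, 0):min(i1, self.current.size)]


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    condition: Condition
    solution: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")


@dataclass
class SegmentAnnotation:
    """Ordered, non-overlapping labeled time intervals of a trace."""

    segments: List[Segment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start + 1e-12:
                raise ValueError(f"overlapping segments at t={b.start}")
        self.segments = segs

    def by_condition(self, condition: Condition) -> List[Segment]:
        return [s for s in self.segments if s.condition == condition]

    def preceding(self, seg: Segment) -> Optional[Segment]:
        prev = None
        for s in self.segments:
            if s.start >= seg.start:
                break
            prev = s
        return prev

    def validate_against(self, trace: Trace) -> None:
        if self.segments and self.segments[-1].end > trace.duration + trace.dt:
            raise ValueError("annotation extends beyond trace duration")


@dataclass
class OocyteMeasurement:
    """Per-oocyte condition-difference currents, stored as magnitudes."""

    oocyte_id: str
    batch_id: str
    group: str
    delta_i_ami: float
    delta_i_camg: float = 0.0

    def __post_init__(self) -> None:
        if not self.batch_id:
            raise ValueError("batch_id must be non-empty")
        if self.delta_i_ami < 0 or self.delta_i_camg < 0:
            raise ValueError("condition-difference currents are magnitudes (>= 0)")


_COHORT_COLUMNS = ["oocyte_id", "batch_id", "group", "delta_i_ami", "delta_i_camg"]


class CohortTable:
    """Table of per-oocyte measurements plus derived columns.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    column set; derived columns (e.g. ``normalized``) may be appended by
    analysis operations.
    """

    def __init__(self, rows: Iterable[OocyteMeasurement] | pd.DataFrame):
        if isinstance(rows, pd.DataFrame):
            missing = [c for c in _COHORT_COLUMNS if c not in rows.columns]
            if missing:
                raise ValueError(f"cohort table missing columns: {missing}")
            self.df = rows.reset_index(drop=True).copy()
        else:
            self.df = pd.DataFrame(
                [
                    {
                        "oocyte_id": r.oocyte_id,
                        "batch_id": r.batch_id,
                        "group": r.group,
                        "delta_i_ami": r.delta_i_ami,
                        "delta_i_camg": r.delta_i_camg,
                    }
                    for r in rows
                ],
                columns=_COHORT_COLUMNS,
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> List[str]:
        return list(self.df["group"].unique())

    def rows(self) -> List[OocyteMeasurement]:
        return [
            OocyteMeasurement(
                r.oocyte_id, r.batch_id, r.group, r.delta_i_ami, r.delta_i_camg
            )
            for r in self.df.itertuples()
        ]


def nernst_potential(
    z: int, c_out: float, c_in: float, constants: PhysConstants = PhysConstants()
) -> float:
    """Equilibrium potential (mV) for an ion of valence ``z``.

    Returns (RT/F / z) * ln(c_out / c_in).
    """
    if z == 0:
        raise ValueError("valence z must be non-zero")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    return constants.rt_over_f / z * math.log(c_out / c_in)


def effective_potential(
    holding: float, constants: PhysConstants = PhysConstants()
) -> float:
    """Liquid-junction-corrected trans-patch potential (mV).

    A bath-positive junction potential makes the effective potential more
    negative: returns ``holding - lj_potential``.
    """
    return holding - constants.lj_potential
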