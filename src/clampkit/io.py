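"""Plain-text I/O: trace CSV, sidecar annotation JSON, cohort CSV,
timecourse CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .core import CohortTable, Condition, Segment, SegmentAnnotation, Trace
from .retrieval import MtsetSeries

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_annotation_json",
    "read_annotation_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_mtset_csv",
    "read_mtset_csv",
]


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.time, "current": trace.current})
    header = f"# units={trace.units} dt={trace.dt} label={trace.label}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> Trace:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = dict(kv.split("=", 1) for kv in first[1:].split())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    times = df["time_s"].to_numpy()
    dt = float(meta.get("dt", times[1] - times[0] if len(times) > 1 else 1.0))
    return Trace(
        dt,
        df["current"].to_numpy(),
        units=meta.get("units", "nA"),
        label=meta.get("label", ""),
    )


def write_annotation_json(ann: SegmentAnnotation, path: str | Path) -> None:
    payload = [
        {
            "start": s.start,
            "end": s.end,
            "condition": s.condition.value,
            "solution": s.solution,
        }
        for s in ann.segments
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation_json(path: str | Path) -> SegmentAnnotation:
    payload = json.loads(Path(path).read_text())
    return SegmentAnnotation(
        [
            Segment(d["start"], d["end"], Condition(d["condition"]), d.get("solution", ""))
            for d in payload
        ]
    )


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def write_mtset_csv(series_list: List[MtsetSeries], path: str | Path) -> None:
    """Long-format per-oocyte timecourse CSV.

    Columns: oocyte_id, t_min, delta_i_ami, di_before, di_second.
    ``di_before``/``di_second`` repeat on every row of an oocyte.
    """
    rows = []
    for s in series_list:
        for t, v in s.di_t.items():
            rows.append(
                {
                    "oocyte_id": s.oocyte_id,
                    "t_min": t,
                    "delta_i_ami": v,
                    "di_before": s.di_before,
                    "di_second": s.di_second_mtset,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mtset_csv(path: str | Path) -> List[MtsetSeries]:
    df = pd.read_csv(path)
    out = []
    for oid, g in df.groupby("oocyte_id", sort=False):
        out.append(
            MtsetSeries(
                di_before=float(g["di_before"].iloc[0]),
                di_t={float(t): float(v) for t, v in zip(g["t_min"], g["delta_i_ami"])},
                di_second_mtset=float(g["di_second"].iloc[0]),
                oocyte_id=str(oid),
            )
        )
    return out
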