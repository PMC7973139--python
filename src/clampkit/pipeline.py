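"""End-to-end orchestration: simulate -> analyze -> infer -> report.

A single YAML/dict config drives every stage; identical config + seed
produce byte-identical numeric outputs.  Each run writes a provenance
block (seed, package version, config SHA-256) into the summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, io, iv, metrics, retrieval, synth, trafficking
from .core import CohortTable, PhysConstants
from .iv import StepProtocol
from .synth import CohortSpec, GatingSpec, GroupSpec
from .trafficking import TraffickingParams

__all__ = ["RunConfig", "default_config", "run_pipeline"]


def default_config(seed: int = 0) -> Dict[str, Any]:
    """Small demo configuration exercising every stage."""
    return {
        "seed": seed,
        "cohort": {
            "n_oocytes": 20,
            "n_batches": 3,
            "noise_sd": 5.0,
            "expression_cv": 0.5,
            "groups": [
                {"name": "control", "mean_di_ami_uA": 5.0},
                {
                    "name": "test",
                    "mean_di_ami_uA": 5.0,
                    "inhibition": 0.54,
                    "camg_scale_uA": 0.8,
                },
            ],
        },
        "mtset": {
            "n_oocytes": 12,
            "remaining_fraction": 0.46,
            "po_baseline": 0.3,
            "t_final": 70.0,
            "noise_sd": 0.02,
            "n0": 1000.0,
            "unitary": 0.001,
        },
        "iv": {
            "conductance_uS": 2.0,
            "erev_na": -15.3,
            "erev_nmdg": -35.1,
            "background_uS": 1.0,
            "background_erev": -35.0,
            "noise_sd": 0.0,
        },
        "patch": {
            "n_channels": 2,
            "p_open": 0.3,
            "unitary_pA": 0.38,
            "noise_sd": 0.05,
            "duration_s": 40.0,
            "amiloride_tail_s": 8.0,
            "holding_mV": -70.0,
        },
    }


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    config: Dict[str, Any]
    out_dir: Path

    @classmethod
    def from_dict(cls, config: Dict[str, Any], out_dir: str | Path) -> "RunConfig":
        required = {"seed", "cohort", "mtset", "iv", "patch"}
        missing = required - set(config)
        if missing:
            raise ValueError(f"config missing sections: {sorted(missing)}")
        return cls(int(config["seed"]), config, Path(out_dir))


def _config_hash(config: Dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_cohort(cfg: Dict[str, Any], seed: int, out: Path) -> Dict[str, Any]:
    c = cfg["cohort"]
    spec = CohortSpec(
        n_oocytes=c["n_oocytes"],
        n_batches=c["n_batches"],
        groups=tuple(GroupSpec(**g) for g in c["groups"]),
        expression_cv=c.get("expression_cv", 0.5),
        noise_sd=c.get("noise_sd", 5.0),
        seed=seed,
    )
    bundle = synth.generate_cohort(spec)
    measured = []
    for oid, (trace, ann) in bundle.traces.items():
        row = bundle.truth.df[bundle.truth.df["oocyte_id"] == oid].iloc[0]
        measured.append(
            {
                "oocyte_id": oid,
                "batch_id": row["batch_id"],
                "group": row["group"],
                "delta_i_ami": metrics.measure_delta_ami(trace, ann),
                "delta_i_camg": metrics.measure_divalent_removal(trace, ann),
            }
        )
    cohort = metrics.batch_normalize(
        CohortTable(pd.DataFrame(measured)),
        control_group=c["groups"][0]["name"],
    )
    io.write_cohort_csv(cohort, out / "cohort_measured.csv")
    io.write_cohort_csv(bundle.truth, out / "cohort_truth.csv")
    summary = metrics.summarize_groups(cohort)
    control = c["groups"][0]["name"]
    rel = {}
    for g in cohort.groups:
        if g == control:
            continue
        sub = cohort.df[cohort.df["group"] == g]
        rel[g] = float(
            np.mean(
                [metrics.relative_inhibition(v, 1.0) for v in sub["normalized"]]
            )
        )
    return {
        "group_summary": json.loads(summary.to_json(orient="index")),
        "relative_inhibition_pct": rel,
    }


def _mtset_params(m: Dict[str, Any]) -> TraffickingParams:
    lam = math.log(1.0 / m["remaining_fraction"]) / m["t_final"]
    return trafficking.steady_state(
        TraffickingParams(
            lambda_ret=lam,
            j_ins=0.0,
            n0=m.get("n0", 1000.0),
            po_baseline=m["po_baseline"],
            unitary=m.get("unitary", 0.001),
        )
    )


def _stage_mtset(cfg: Dict[str, Any], seed: int, out: Path) -> Dict[str, Any]:
    m = cfg["mtset"]
    params = _mtset_params(m)
    times = tuple(np.arange(0.0, m["t_final"] + 1e-9, 10.0))
    series = synth.simulate_mtset_cohort(
        params,
        n_oocytes=m["n_oocytes"],
        noise_sd=m.get("noise_sd", 0.02),
        seed=seed + 1,
        sample_times=times,
    )
    io.write_mtset_csv(series, out / "mtset_timecourse.csv")
    estimates = [retrieval.retrieval_current(s) for s in series]
    x = [s.di_t[0.0] for s in series]
    y = [e.di_retrieval for e in estimates]
    k, se = retrieval.proportional_fit(x, y)
    pd.DataFrame(
        [
            {
                "oocyte_id": s.oocyte_id,
                "po_initial": e.po_initial,
                "di_insertion": e.di_insertion,
                "di_retrieval": e.di_retrieval,
                "remaining_fraction_corrected": e.remaining_fraction_corrected,
            }
            for s, e in zip(series, estimates)
        ]
    ).to_csv(out / "mtset_estimates.csv", index=False)
    return {
        "true_remaining_fraction": m["remaining_fraction"],
        "mean_remaining_fraction_corrected": float(
            np.mean([e.remaining_fraction_corrected for e in estimates])
        ),
        "mean_po_initial": float(np.mean([e.po_initial for e in estimates])),
        "proportional_k": k,
        "proportional_k_se": se,
    }


def _stage_iv(cfg: Dict[str, Any], seed: int, out: Path) -> Dict[str, Any]:
    v = cfg["iv"]
    protocol = StepProtocol()
    constants = PhysConstants()

    def _curve(g, erev, s):
        traces = synth.simulate_step_protocol(
            g, erev, protocol, noise_sd=v.get("noise_sd", 0.0), seed=s
        )
        return iv.build_iv(traces, protocol)

    bg = v.get("background_uS", 0.0)
    bge = v.get("background_erev", -35.0)
    # test oocyte = channel conductance + endogenous background; control
    # oocyte = background alone (same batch)
    curve_na = _curve(v["conductance_uS"] + bg, _mixed_erev(v["conductance_uS"], v["erev_na"], bg, bge), seed + 2)
    curve_nmdg = _curve(v["conductance_uS"] + bg, _mixed_erev(v["conductance_uS"], v["erev_nmdg"], bg, bge), seed + 3)
    control_na = _curve(bg, bge, seed + 4)
    control_nmdg = _curve(bg, bge, seed + 5)
    corr_na = iv.subtract_background(curve_na, control_na)
    corr_nmdg = iv.subtract_background(curve_nmdg, control_nmdg)
    erev_na = iv.estimate_reversal(corr_na)
    erev_nmdg = iv.estimate_reversal(corr_nmdg)
    shift = erev_nmdg - erev_na
    ratio = iv.permeability_ratio(shift, constants)
    pd.DataFrame(
        {
            "V_mV": corr_na.potentials,
            "I_na": corr_na.currents,
            "I_nmdg": corr_nmdg.currents,
        }
    ).to_csv(out / "iv_corrected.csv", index=False)
    return {
        "erev_na_corrected": erev_na,
        "erev_nmdg_corrected": erev_nmdg,
        "delta_erev": shift,
        "permeability_ratio": ratio,
    }


def _mixed_erev(g1: float, e1: float, g2: float, e2: float) -> float:
    """Reversal of the sum of two ohmic conductances."""
    return (g1 * e1 + g2 * e2) / (g1 + g2) if g1 + g2 > 0 else 0.0


def _stage_patch(cfg: Dict[str, Any], seed: int, out: Path) -> Dict[str, Any]:
    from . import single_channel as sc

    p = cfg["patch"]
    spec = GatingSpec.from_po(
        p["n_channels"], p["p_open"], p["unitary_pA"], noise_sd=p.get("noise_sd", 0.05)
    )
    trace, ann = synth.simulate_single_channel(
        spec,
        duration=p.get("duration_s", 40.0),
        amiloride_tail=p.get("amiloride_tail_s", 8.0),
        seed=seed + 6,
    )
    io.write_trace_csv(trace, out / "patch_trace.csv")
    io.write_annotation_json(ann, out / "patch_trace.json")
    result = sc.analyze_patch(trace, ann, holding=p.get("holding_mV", -70.0))
    return {
        "i_pA": result.i,
        "apparent_n": result.apparent_n,
        "npo": result.npo,
        "po_app": result.po_app,
        "conductance_pS": result.conductance_pS,
        "true_i_pA": p["unitary_pA"],
        "true_npo": p["n_channels"] * p["p_open"],
    }


def run_pipeline(config: Dict[str, Any], out_dir: str | Path) -> Dict[str, Any]:
    """Execute all stages and write a JSON summary with provenance."""
    rc = RunConfig.from_dict(config, out_dir)
    rc.out_dir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, Any] = {
        "provenance": {
            "seed": rc.seed,
            "version": __version__,
            "config_sha256": _config_hash(rc.config),
        }
    }
    stages = {
        "cohort": _stage_cohort,
        "mtset": _stage_mtset,
        "iv": _stage_iv,
        "patch": _stage_patch,
    }
    for name, fn in stages.items():
        try:
            summary[name] = fn(rc.config, rc.seed, rc.out_dir)
        except Exception as exc:  # noqa: BLE001 - stage context matters
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    (rc.out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
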