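# clampkit

Simulation and analysis toolkit for oocyte voltage-clamp experiments on
surface ion channels. It implements, as a reusable and tested pipeline:

- **Whole-cell current metrics** — amiloride-sensitive current (ΔI_Ami),
  divalent-removal hemichannel current, relative inhibition, fold
  stimulation, batch-matched normalization, and mean ± SEM / n / N
  cohort summaries (`clampkit.metrics`).
- **I/V analysis** — I/V curves from the final 100 ms of 2 s voltage
  steps, reversal-potential estimation, control-mean background
  subtraction, and cation permeability ratios from reversal-potential
  shifts, P_X/P_Na = exp(ΔE_rev·F/RT) (`clampkit.iv`).
- **Forward trafficking model** — a two-pool surface-channel model
  (first-order retrieval, constant insertion, instantaneous covalent
  open-probability locking) with closed-form dynamics
  (`clampkit.trafficking`).
- **Retrieval inference** — the sulfhydryl-reagent two-application
  calculus: P_o(initial), ΔI_Insertion, ΔI_Retrieval, normalized decay,
  the corrected remaining fraction, and proportional (through-origin)
  regression across oocytes (`clampkit.retrieval`).
- **Single-channel analysis** — closed-level anchoring in amiloride,
  250 Hz refiltering, binned amplitude histograms, unitary amplitude,
  NP_o, apparent channel count, P_o(app), and chord conductance at the
  liquid-junction-corrected potential (`clampkit.single_channel`).
- **Synthetic data** — deterministic generators with known ground truth
  for annotated whole-cell cohorts (lognormal expression and batch
  heterogeneity), modification-protocol timecourses, step-protocol
  recordings, and stochastic two-state multi-channel patches
  (`clampkit.synth`).
- **Physical constants & solutions** — Nernst potentials, liquid-junction
  correction (RT/F = 25.5 mV, LJ = 12 mV defaults), and solution presets
  with explicitly stored total chloride (`clampkit.core`).

## CLI

```sh
clampkit simulate cohort --seed 1 --out out/cohort      # traces + truth
clampkit analyze --traces out/cohort/traces \
    --truth out/cohort/cohort_truth.csv --out out/measured.csv
clampkit simulate iv --erev -35.1 --out out/iv
clampkit iv-fit --traces out/iv --out out/iv_fit
clampkit simulate mtset --seed 1 --out out/mtset.csv
clampkit mtset-infer --timecourse out/mtset.csv --out out/mtset_est
clampkit simulate patch --out out/patch
clampkit patch-analyze --trace out/patch.csv --out out/patch_result
clampkit run --config configs/demo.yaml --seed 1 --out out/full   # everything
```

Traces are CSV (`time_s,current` with a `# units=... dt=...` header),
segment annotations are sidecar JSON, cohorts and timecourses are CSV,
and every pipeline run writes a `summary.json` with provenance (seed,
version, config hash). Reruns with the same config and seed are
byte-identical.

## Conventions

- Raw trace currents are signed (inward negative); condition-difference
  metrics are reported as non-negative magnitudes.
- Relative inhibition is reported positive-for-inhibition (the raw ratio
  formula gives negative values; the sign is flipped once, centrally).
- Plateaus are means over the final 20% of a segment (configurable via
  `MetricWindows`).
- The thermal voltage defaults to 25.5 mV and the liquid-junction
  correction to 12 mV (bath positive); both are configurable through
  `PhysConstants`.
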