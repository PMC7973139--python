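seed: 1
cohort:
  n_oocytes: 20
  n_batches: 3
  noise_sd: 5.0
  expression_cv: 0.5
  groups:
  - name: control
    mean_di_ami_uA: 5.0
  - name: test
    mean_di_ami_uA: 5.0
    inhibition: 0.54
    camg_scale_uA: 0.8
mtset:
  n_oocytes: 12
  remaining_fraction: 0.46
  po_baseline: 0.3
  t_final: 70.0
  noise_sd: 0.02
  n0: 1000.0
  unitary: 0.001
iv:
  conductance_uS: 2.0
  erev_na: -15.3
  erev_nmdg: -35.1
  background_uS: 1.0
  background_erev: -35.0
  noise_sd: 0.0
patch:
  n_channels: 2
  p_open: 0.3
  unitary_pA: 0.38
  noise_sd: 0.05
  duration_s: 40.0
  amiloride_tail_s: 8.0
  holding_mV: -70.0
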