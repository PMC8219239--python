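# Run configuration schema

`spiraltrem run --config run.yaml` accepts the fields of `RunConfig`.
Exactly one input mode is used: `synthetic`, or the real-data paths.

```yaml
seed: 11                     # drives all randomness; also overrides synthetic.seed
selection_threshold: 0.05    # p-threshold carrying features from experiment 1 to 2
alpha: 0.05                  # table flag threshold (bilateral)
alpha_strict: 0.01           # strong flag threshold; must be <= alpha
surface_only: true           # restrict features to on-surface strokes
out_dir: demo_out            # optional; tables + report written here

# --- synthetic mode ---------------------------------------------------
synthetic:
  n_subjects: 19
  level_range: [2, 45]       # integer tremor-score range
  brainvol_mean: 1.1e6       # mm^3
  brainvol_sd: 1.0e5
  tremor_per_level: 0.15     # tablet units of tremor amplitude per score point
  subject_gain_sd: 0.3       # sd of per-subject log tremor gain
  seed: 11
  spiral:                    # per-trial simulation (SpiralSimConfig fields)
    duration_s: 10.0
    fs: 100
    tremor_freq_hz: 5.0
  roi_effects:               # region -> linear coupling
    rh_Thalamus: {beta_level: -12.0, beta_brainvol: 0.002, noise_sd: 80.0}
    lh_Somato_Motor_A: {beta_level: 25.0, beta_brainvol: 0.004, noise_sd: 160.0}

# --- real-data mode (instead of synthetic) ----------------------------
# recordings:                # subject id -> SVC file
#   P01: data/P01.svc
# covariates_path: data/covariates.tsv   # subject, tremor_level, brain_volume
# roi_paths:                 # family -> [path, measure]
#   subcortical: [data/aseg.tsv, subcortical_volume]
#   cortical_ct: [data/ct.tsv, CT]
```

Measures are `CV`, `CT`, `subcortical_volume`, `network_volume`. ROI table
files are delimiter-separated with a `subject` first column and region-name
columns (`lh_precentral_part7`, `lh_ct_precentral_part7`, `rh_Thalamus`,
`lh_Somato_Motor_A`, ...).
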