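# Demo configuration for `pathscore run --config configs/demo.yaml --out-dir <dir>`
# Simulates a calibration set and an 8-patient longitudinal relapse study,
# calibrates the model, scores every sample, and runs the fold-change and
# differential-correlation analyses.
seed: 42
calibration:
  n_active: 25
  n_inactive: 25
  noise_sd: 0.5
longitudinal:
  n_patients: 8
  activity_shift_at_relapse: 0.6
  bcl2a1_upregulated_fraction: 0.625
  fold_change_magnitude: 4.0
  noise_sd: 0.5
  couple_bcl2_to_pathway: true
foldchange:
  threshold: 2.0
  baseline: diagnosis
  followup: induction_2
correlate:
  anchor: BCL2A1
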