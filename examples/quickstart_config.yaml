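# Minimal end-to-end experiment: simulated resting subject, semantic
# segmentation, personalized sliding-window evaluation.
source:
  simulate:
    preset: rest
    duration_s: 120.0
smooth:
  enabled: true
  order: 3
  window: 5
segmentation:
  mode: semantic
  max_hr_bpm: 200
  prominence_frac: 0.3
  min_cycle_s: 0.33
  max_cycle_s: 2.0
  ecg_polarity: positive
representation:
  L: 300
  coeffs: auto          # or "capnobase", or [n_ppg, n_ecg]
  energy_threshold: 0.9998
model:
  gamma: 1.0
  gamma_search: false
evaluation:
  scheme: personalized  # or general-cv, loso
  window: 20
  train_frac: 0.8
  stride: null
  compute_rrmse: false
seed: 1
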