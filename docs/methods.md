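# Methods

## Problem and model

The package reconstructs per-beat ECG waveforms from a synchronized PPG
channel. The unit of analysis is the cardiac cycle: the PPG between two
consecutive systolic peaks, paired with an ECG segment that is either the
samples at the same timestamps (*direct* mode) or the R-to-R interval of the
same beats (*semantic* mode). After resampling every cycle to a fixed length
L and min–max normalizing it, each cycle is represented by its first n
orthonormal DCT-II coefficients. The transfer function between the PPG and
ECG coefficient spaces is ridge regression in closed form,
f\* = (XᵀX + γI)⁻¹XᵀY, and reconstruction is DCT → f\* → zero-pad → inverse
DCT. The model is linear by design: the point of the package is to
characterize what the linear cycle-to-cycle map can and cannot recover, not
to maximize reconstruction accuracy.

Assumptions worth making explicit: one PPG cycle carries enough information
to determine the paired ECG cycle's coefficients linearly; cycles are
morphologically stationary within a training window; the R peak is the
dominant positive deflection of a normalized ECG cycle (a polarity flag
handles inverted leads); and the pulse-arrival time (PAT) is short relative
to the RR interval, so the R peak generating a systolic peak is the latest R
at or before it — the rule the semantic pairing uses.

## Parameters

| parameter | default | meaning |
|---|---|---|
| Savitzky–Golay order / window | 3 / 5 samples | phase-free smoothing; order 3 reproduces cubic trends exactly |
| `max_hr_bpm` | 200 | minimum peak spacing 60/200 s for both detectors |
| `prominence_frac` | 0.3 | prominence threshold as a fraction of the robust (5th–95th pct) range |
| systolic `presmooth_s` | 0.05 s | centered moving average before systolic argmax (see below) |
| cycle duration band | 0.33–2.0 s | ≈180 down to 30 BPM; guards resampling against artifact cycles |
| L | 300 samples | fixed cycle length; conservative bound on ~200-sample cycles at 300 Hz |
| energy threshold | 0.9998 | smallest n with mean captured-energy fraction ≥ threshold, on training cycles only |
| γ | 1.0 | ridge penalty; optional log-grid search (1e−6…1e3) on a chronological inner split |
| window / train_frac / stride | 20 / 0.8 / 20 cycles | personalized pooled sliding-window split |

The `capnobase` preset (n_ppg = 11, n_ecg = 100) carries the coefficient
counts reported for 300 Hz clinical benchmark recordings at the 99.98%
threshold, for runs that should skip data-driven selection.

## Numerical choices

* **DCT convention.** Orthonormal DCT-II, so Parseval holds exactly
  (Σx² = Σc²) and the energy-threshold rule is well defined. The threshold is
  aggregated as the *mean* captured-energy fraction over training cycles;
  percentile rules were rejected as needless complexity.
* **Ridge solve.** Cholesky factorization of XᵀX + γI; explicit inversion is
  avoided. At γ = 0 a singular Gram matrix raises an error suggesting γ > 0.
  No intercept, no standardization: the closed form is applied literally to
  normalized-cycle coefficients.
* **Savitzky–Golay boundaries.** Edge samples come from a polynomial fit to
  the first/last window (scipy `mode="interp"`). This keeps output length
  equal to input length *and* preserves the filter's defining property —
  exact reproduction of polynomials up to the filter order — which mirror
  extension would break at the edges. The same filter is applied to both
  channels.
* **Systolic detection.** The systolic peak is broad (σ ≈ 0.1 s), so its raw
  argmax is noise-sensitive; a 50 ms centered moving average (zero phase) is
  applied before peak picking. R detection runs unsmoothed — the R spike is
  sharp enough that smoothing would do more harm than good. The dicrotic wave
  biases the detected systolic peak late by a few milliseconds; evaluation
  tolerances account for this.
* **Degenerate inputs.** Constant cycles normalize to all-zeros with a
  scale-0 flag; constant sequences yield an undefined (NaN) correlation that
  aggregates exclude and count rather than impute; cycles shorter than 2
  samples are rejected as degenerate.
* **R-delay convention.** The reconstructed R time is the argmax of the
  normalized reconstruction laid onto the *PPG cycle's* timestamps — the only
  timing that exists at inference. This makes the semantic-mode delay equal
  the PAT by construction (the reconstruction starts at an R shape, the cycle
  starts at a systolic peak), which is precisely the information the semantic
  alignment threw away; reporting it as delay is the honest accounting.
* **Concatenation layout.** For the correlation-decay experiment, direct-mode
  reconstructions are laid out at their own cycle durations (their timing is
  real: perfect reconstructions tile the record, ρ ≈ 1 for all k). Semantic
  reconstructions are generic R-to-R cycles with no beat-duration
  information, so they are laid out at the subject's mean cycle length; RR
  variability then accumulates as misalignment and ρ decays with k. Laying
  semantic pieces out at per-cycle PPG durations is also supported
  (`durations="cycle"`), but the layout error then telescopes — bounded by
  PAT jitter — and the decay saturates, understating the loss of HRV
  information.

## The simulator

The synthetic generator emulates the features of clinical PPG/ECG that the
pipeline is sensitive to: quasi-periodic beats with AR(1) RR variability
(lag-1 coefficient 0.6), abrupt heart-rate bursts (mean HR overridden inside
a window, as seen intra-operatively), five-Gaussian P-QRS-T morphology with R
the per-beat maximum, systolic + dicrotic PPG waves delayed by a configurable
PAT with beat-to-beat jitter, per-channel white noise at a target SNR, and —
for population experiments — per-subject perturbation of wave amplitudes,
offsets, widths and PAT. HR variability maps to RR variability to first
order, rr_sd = 60·hr_sd/hr_mean².

It does **not** emulate baseline wander, motion artifacts, respiratory
modulation, arrhythmic or diseased morphology, or optical sensor physics.
Passing tests therefore demonstrate the correctness and internal logic of the
pipeline — segmentation fidelity, transform/solver exactness, the
morphology-vs-timing trade-off, the personalization gap, concatenation decay
— not clinical-grade performance on real recordings, where absolute scores
will be lower and detector failure handling matters more.

Default study conditions used by the tests and the acceptance script: a
10-minute subject at 70 BPM with 40 ms RR variability, one 60 s burst to
100 BPM, PAT 0.25 s with 10 ms jitter, 25 dB SNR; populations of 10 subjects
at 120 s each with morphology/PAT variation 0.4. These sizes keep a full run
in seconds while giving several hundred cycles per subject.

## Design choices that were genuinely open

* **Semantic pairing rule.** "Between two R peaks" underdetermines *which*
  R-R interval; the latest R at or before the systolic peak is chosen because
  the R that generates a systolic peak precedes it by the PAT. Unpairable or
  doubly claimed intervals are dropped (keeping pairing one-to-one) rather
  than interpolated, so train/test counts stay honest.
* **Personalized split granularity.** One model per subject on the pooled
  window-train cycles, not one model per 20-cycle window: 16 cycles cannot
  determine an 11×100 map, and the split's purpose is an even heart-rate mix
  between train and test, which pooling preserves.
* **γ default.** A fixed, documented γ = 1.0 keeps runs reproducible;
  grid-search is opt-in because the inner split costs cycles and the
  coefficient scales put γ ≈ 1 in a reasonable shrinkage regime.
* **Min–max amplitude normalization** per cycle: scale-free, invertible, and
  irrelevant to the Pearson metric; alternatives (z-scoring) would change
  nothing the evaluation measures.

## Known limitations

* The linear map cannot represent beat-position dependence, so direct-mode
  morphology degrades with HRV by construction — that is a finding, not a
  bug, but it means direct-mode ρ is sensitive to the simulated HRV level.
* Peak-detector parameters are tuned for cleaned or simulated signals;
  heavily artifacted records need the duration filter and trimming config to
  do real work.
* `select_coeff_count` on noisy cycles counts noise energy, inflating n;
  coefficient counts reported on synthetic noisy data are therefore larger
  than counts on clean clinical averages.
* Single-lead, positive-R assumption (flag for inverted polarity); no
  arrhythmia-aware beat classification.
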