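"""Compress normalized cycles with an energy-thresholded DCT.

Every cycle is resampled to L=300 samples, normalized to [0,1] and
represented by its first n orthonormal DCT-II coefficients, where n is
the smallest count whose mean captured-energy fraction reaches 99.98%.
"""

import numpy as np

from ppg2ecg import (
    SimConfig,
    dct_forward,
    dct_inverse,
    select_coeff_count,
    simulate_record,
)
from ppg2ecg.pipeline import ExperimentConfig, segment_record
from ppg2ecg.representation import normalize_pair

sim = simulate_record(SimConfig(duration_s=120.0, hr_sd_bpm=2.0, seed=3))
ec = ExperimentConfig()
ec.segmentation["mode"] = "semantic"
pairs = segment_record(sim.record, ec)
norm = [normalize_pair(p) for p in pairs]
ppg_cycles = [c[0] for c in norm]
ecg_cycles = [c[1] for c in norm]

n_ppg = select_coeff_count(ppg_cycles, 0.9998)
n_ecg = select_coeff_count(ecg_cycles, 0.9998)
print(f"cycles: {len(pairs)}  (L = 300 samples each)")
print(f"coefficients at 99.98% energy:  PPG {n_ppg}   ECG {n_ecg}")

errs = []
for c in ecg_cycles:
    recon = dct_inverse(dct_forward(c.values, n_ecg))
    errs.append(np.max(np.abs(recon - c.values)))
print(f"max truncation error on ECG cycles: {np.max(errs):.4f} (normalized units)")
print()
print("The smooth PPG pulse needs far fewer coefficients than the")
print("morphologically rich ECG; truncation at 99.98% energy leaves the")
print("QRS shape essentially intact.")
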