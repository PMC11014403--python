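"""Compare segmentation modes and evaluation protocols.

Runs the personalized sliding-window protocol for both segmentation
modes on one subject, then contrasts personalized and
leave-one-subject-out scores on a heterogeneous population.
"""

import numpy as np

from ppg2ecg import (
    PipelineParams,
    SimConfig,
    build_loso,
    build_personalized_windows,
    run_scheme,
    simulate_record,
    simulate_subject_population,
)
from ppg2ecg.pipeline import ExperimentConfig, segment_record

# --- one subject, 10 minutes, with an HR burst: the trade-off ----------
cfg = SimConfig(
    duration_s=600.0,
    hr_mean_bpm=70.0,
    hr_sd_bpm=3.27,  # 40 ms RR variability
    hr_burst=(240.0, 100.0, 60.0),
    pat_s=0.25,
    pat_sd_s=0.01,
    noise_snr_db=25.0,
    seed=3,
)
sim = simulate_record(cfg)
params = PipelineParams()
print("segmentation   mean rho   mean R delay [s]   (personalized)")
for mode in ("direct", "semantic"):
    ec = ExperimentConfig()
    ec.segmentation["mode"] = mode
    pairs = segment_record(sim.record, ec)
    s = run_scheme(build_personalized_windows(pairs), pairs, params).summary()
    print(f"{mode:<12}   {s['mean_rho']:.4f}     {s['mean_r_delay_s']:.4f}")
print()

# --- ten heterogeneous subjects: personalization gap -------------------
base = SimConfig(duration_s=120.0, hr_sd_bpm=2.0, noise_snr_db=25.0)
sims = simulate_subject_population(10, base, subject_variation=0.4, seed=0)
ec = ExperimentConfig()
by_subj = {s.record.subject_id: segment_record(s.record, ec) for s in sims}
pers = []
for ps in by_subj.values():
    pers.append(run_scheme(build_personalized_windows(ps), ps, params).per_cycle["rho"])
pers_rho = float(np.nanmean(np.concatenate([p.to_numpy() for p in pers])))
allp = [p for ps in by_subj.values() for p in ps]
loso_rho = float(np.nanmean(run_scheme(build_loso(allp), allp, params).per_cycle["rho"]))
print(f"population (semantic): personalized rho {pers_rho:.4f}  vs  LOSO rho {loso_rho:.4f}")
print()
print("Semantic alignment buys morphology at the cost of R timing; a model")
print("trained on other subjects loses correlation because QRS morphology")
print("and pulse-arrival time are person-specific.")
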