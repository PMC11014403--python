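import numpy as np
import pytest

from ppg2ecg import SimConfig, simulate_record
from ppg2ecg.segmentation import CyclePair


@pytest.fixture(scope="session")
def clean_sim():
    """60 s noiseless record at 70 BPM with mild HRV, PAT 0.25 s."""
    cfg = SimConfig(duration_s=60.0, hr_mean_bpm=70.0, hr_sd_bpm=2.0, pat_s=0.25, seed=11)
    return simulate_record(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """60 s record at 20 dB SNR, same beat structure as clean_sim."""
    cfg = SimConfig(
        duration_s=60.0,
        hr_mean_bpm=70.0,
        hr_sd_bpm=2.0,
        pat_s=0.25,
        noise_snr_db=20.0,
        seed=11,
    )
    return simulate_record(cfg)


def make_dummy_pairs(n, subject_id="S", start=0.0, dur=1.0, mode="direct"):
    """Fabricate minimal cycle pairs for split-plan tests."""
    rng = np.random.default_rng(0)
    pairs = []
    t = start
    for i in range(n):
        x = rng.standard_normal(30)
        pairs.append(
            CyclePair(
                ppg_raw=x,
                ecg_raw=x.copy(),
                ppg_start_s=t,
                ecg_start_s=t,
                fs=30.0,
                r_time_true_s=t + 0.5 * dur,
                subject_id=subject_id,
                mode=mode,
            )
        )
        t += dur
    return pairs
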