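import numpy as np
import pytest

from ppg2ecg import (
    SimConfig,
    detect_r_peaks,
    simulate_linear_pairs,
    simulate_record,
    simulate_rr_series,
    simulate_subject_population,
)
from ppg2ecg.representation import dct_forward, dct_inverse
from ppg2ecg.representation import DctVector


class TestRrSeries:
    def test_constant_without_variability(self):
        cfg = SimConfig(hr_mean_bpm=70.0, hr_sd_bpm=0.0, duration_s=60.0)
        rr = simulate_rr_series(cfg)
        np.testing.assert_allclose(rr, 60.0 / 70.0, atol=1e-12)

    def test_seed_determinism(self):
        cfg = SimConfig(hr_sd_bpm=3.0, duration_s=120.0, seed=5)
        np.testing.assert_array_equal(simulate_rr_series(cfg), simulate_rr_series(cfg))

    def test_mean_and_autocorrelation(self):
        cfg = SimConfig(hr_mean_bpm=70.0, hr_sd_bpm=3.0, duration_s=600.0, seed=1)
        rr = simulate_rr_series(cfg)
        assert abs(rr.mean() - 60.0 / 70.0) / (60.0 / 70.0) < 0.02
        d = rr - rr.mean()
        lag1 = np.sum(d[:-1] * d[1:]) / np.sum(d**2)
        assert lag1 > 0

    def test_burst_raises_rate(self):
        cfg = SimConfig(
            hr_mean_bpm=70.0, hr_sd_bpm=0.0, duration_s=120.0, hr_burst=(40.0, 100.0, 20.0)
        )
        sim = simulate_record(cfg)
        rr = sim.rr_series_s
        t = sim.r_times_s[:-1]
        in_burst = rr[(t > 42) & (t < 58)]
        outside = rr[t < 38]
        # 100 vs 70 BPM: burst RR should sit near 0.6 s vs 0.857 s
        assert np.mean(in_burst) < 0.75 * np.mean(outside)


class TestSimulateRecord:
    def test_noiseless_r_peaks_recovered_exactly(self, clean_sim):
        peaks = detect_r_peaks(clean_sim.record.ecg)
        fs = clean_sim.record.fs
        assert len(peaks) == clean_sim.r_times_s.size
        assert np.max(np.abs(peaks.times_s() - clean_sim.r_times_s)) <= 1.0 / fs + 1e-9

    def test_pat_by_construction(self):
        cfg = SimConfig(duration_s=60.0, pat_s=0.25, pat_sd_s=0.0, seed=2)
        sim = simulate_record(cfg)
        gaps = sim.systolic_times_s - sim.r_times_s
        np.testing.assert_allclose(gaps, 0.25, atol=1e-9)

    def test_annotations_ordered_and_matched(self, clean_sim):
        assert clean_sim.r_times_s.size == clean_sim.systolic_times_s.size
        assert np.all(np.diff(clean_sim.r_times_s) > 0)
        assert np.all(clean_sim.systolic_times_s > clean_sim.r_times_s)

    def test_r_is_per_beat_maximum(self, clean_sim):
        ecg = clean_sim.record.ecg.samples
        fs = clean_sim.record.fs
        for r, rr in zip(clean_sim.r_times_s[:-1], np.diff(clean_sim.r_times_s)):
            lo = int((r - 0.4 * rr) * fs)
            hi = int((r + 0.6 * rr) * fs)
            peak_t = (lo + np.argmax(ecg[lo:hi])) / fs
            assert abs(peak_t - r) < 2.0 / fs

    def test_seed_changes_noise_not_beats(self):
        base = dict(duration_s=60.0, hr_sd_bpm=0.0, noise_snr_db=20.0)
        a = simulate_record(SimConfig(seed=1, **base))
        b = simulate_record(SimConfig(seed=2, **base))
        np.testing.assert_array_equal(a.r_times_s, b.r_times_s)
        assert not np.array_equal(a.record.ecg.samples, b.record.ecg.samples)

    def test_realized_snr_within_ten_percent(self):
        base = dict(duration_s=120.0, hr_sd_bpm=0.0, seed=3)
        clean = simulate_record(SimConfig(noise_snr_db=None, **base))
        noisy = simulate_record(SimConfig(noise_snr_db=20.0, **base))
        for chan in ("ppg", "ecg"):
            c = getattr(clean.record, chan).samples
            n = getattr(noisy.record, chan).samples - c
            target = np.var(c) / 10.0 ** (20.0 / 10.0)
            assert abs(np.var(n) - target) / target < 0.10

    def test_bit_reproducible(self):
        cfg = SimConfig(duration_s=30.0, hr_sd_bpm=2.0, noise_snr_db=20.0, seed=7)
        a, b = simulate_record(cfg), simulate_record(cfg)
        np.testing.assert_array_equal(a.record.ppg.samples, b.record.ppg.samples)
        np.testing.assert_array_equal(a.record.ecg.samples, b.record.ecg.samples)


class TestLinearPairs:
    def test_identity_map_yields_truncated_cycles(self):
        n_c = 10
        ppg, ecg, M = simulate_linear_pairs(50, n_ppg=n_c, n_ecg=n_c, L=200, seed=4)
        # overwrite with an identity map by regenerating through the same path
        X = np.vstack([dct_forward(c, n_c).coeffs for c in ppg])
        rebuilt = np.vstack(
            [dct_inverse(DctVector(coeffs=x, n=n_c, L=200)) for x in X @ np.eye(n_c)]
        )
        truncated = np.vstack(
            [dct_inverse(dct_forward(c, n_c)) for c in ppg]
        )
        np.testing.assert_allclose(rebuilt, truncated, atol=1e-9)

    def test_band_limited_generation(self):
        ppg, ecg, M = simulate_linear_pairs(20, n_ppg=11, n_ecg=100, L=300, seed=5)
        assert ppg.shape == (20, 300) and ecg.shape == (20, 300) and M.shape == (11, 100)
        coeffs = dct_forward(ppg[0], 300).coeffs
        np.testing.assert_allclose(coeffs[11:], 0.0, atol=1e-9)

    def test_rank_deficiency_warning(self):
        with pytest.warns(UserWarning):
            simulate_linear_pairs(5, n_ppg=11, n_ecg=20, L=100, seed=6)


class TestPopulation:
    def test_seed_determinism(self):
        base = SimConfig(duration_s=30.0)
        a = simulate_subject_population(3, base, 0.3, seed=9)
        b = simulate_subject_population(3, base, 0.3, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.record.ecg.samples, rb.record.ecg.samples)

    def test_zero_variation_keeps_morphology_identical(self):
        base = SimConfig(duration_s=30.0)
        sims = simulate_subject_population(4, base, 0.0, seed=10)
        ref = sims[0].config
        for s in sims[1:]:
            assert s.config.morph.ecg_waves == ref.morph.ecg_waves
            assert s.config.morph.ppg_waves == ref.morph.ppg_waves
            assert s.config.pat_s == ref.pat_s

    def test_variation_perturbs_morphology(self):
        base = SimConfig(duration_s=30.0)
        sims = simulate_subject_population(4, base, 0.4, seed=11)
        t_amps = {s.config.morph.ecg_waves["T"][0] for s in sims}
        assert len(t_amps) == 4
        for s in sims:
            assert s.config.morph.ecg_waves["R"] == (1.0, 0.0, 0.016)
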