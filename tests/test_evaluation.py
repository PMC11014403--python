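import numpy as np
import pytest
from conftest import make_dummy_pairs

from ppg2ecg import (
    PipelineParams,
    build_general_cv,
    build_loso,
    build_personalized_windows,
    concat_correlation,
    pearson,
    r_peak_delay,
    rrmse,
    run_scheme,
)
from ppg2ecg.errors import ParameterError
from ppg2ecg.pipeline import ExperimentConfig, segment_record
from ppg2ecg.representation import normalize_pair
from ppg2ecg.segmentation import CyclePair


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 5.0])
        # direct covariance formula
        expected = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert pearson(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_flagged_nan(self):
        assert np.isnan(pearson(np.ones(5), np.arange(5.0)))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        assert pearson(3.0 * a + 7.0, b) == pytest.approx(pearson(a, b), abs=1e-12)


class TestRPeakDelay:
    def _pair(self, mode="direct", start=10.0, dur=1.0, r_frac=0.4, fs=300.0):
        n = int(dur * fs)
        return CyclePair(
            ppg_raw=np.zeros(n) + np.arange(n),
            ecg_raw=np.zeros(n) + np.arange(n),
            ppg_start_s=start,
            ecg_start_s=start,
            fs=fs,
            r_time_true_s=start + r_frac * dur,
            subject_id="S",
            mode=mode,
        )

    def test_zero_on_matching_argmax(self):
        pair = self._pair(r_frac=0.4)
        recon = np.zeros(300)
        recon[120] = 1.0  # argmax fraction 120/300 == 0.4
        assert r_peak_delay(recon, pair) == pytest.approx(0.0, abs=1e-12)

    def test_thirty_sample_shift_is_point_one_second(self):
        pair = self._pair(r_frac=0.4)
        recon = np.zeros(300)
        recon[150] = 1.0  # 30 resampled samples past the true R
        assert r_peak_delay(recon, pair) == pytest.approx(0.1, abs=1e-9)

    def test_semantic_mode_delay_is_pat_for_r_aligned_recon(self, clean_sim):
        # a perfect semantic reconstruction starts at the R shape, but is
        # placed at the PPG cycle start: the delay is the pulse-arrival time
        rec = clean_sim.record
        ec = ExperimentConfig()
        ec.segmentation["mode"] = "semantic"
        pairs = segment_record(rec, ec)
        pat = clean_sim.config.pat_s
        for pair in pairs[:20]:
            _, ecg_c = normalize_pair(pair)
            delay = r_peak_delay(ecg_c.values, pair)
            # tolerance: resampling quantization plus a few samples of
            # systolic-detector bias (the dicrotic wave skews the broad peak)
            assert delay == pytest.approx(pat, abs=0.02)


class TestRrmse:
    def test_trivial_values(self):
        gt = np.array([3.0, 4.0])
        assert rrmse(gt, gt) == 0.0
        assert rrmse(np.zeros(2), gt) == 1.0

    def test_brute_force_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        expected = np.sqrt(np.sum((a - b) ** 2)) / np.sqrt(np.sum(b**2))
        assert rrmse(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_reference_flagged(self):
        assert np.isnan(rrmse(np.ones(3), np.zeros(3)))


class TestSplitPlans:
    def test_general_cv_contiguous_folds(self):
        pairs = make_dummy_pairs(100)
        plan = build_general_cv(pairs, k=5)
        all_test = np.concatenate([t for _, t in plan.folds])
        assert sorted(all_test.tolist()) == list(range(100))
        for train, test in plan.folds:
            assert len(test) == 20
            assert np.array_equal(test, np.arange(test[0], test[-1] + 1))
            assert set(train).isdisjoint(set(test))

    def test_general_cv_subject_boundaries(self):
        pairs = (
            make_dummy_pairs(50, "A") + make_dummy_pairs(50, "B") + make_dummy_pairs(50, "C")
        )
        plan = build_general_cv(pairs, k=5)
        subj = np.array([p.subject_id for p in pairs])
        mixed = sum(1 for _, test in plan.folds if len(set(subj[test])) > 1)
        assert mixed <= 2

    def test_personalized_window_index_arithmetic(self):
        pairs = make_dummy_pairs(40)
        plan = build_personalized_windows(pairs, window=20, train_frac=0.8, stride=20)
        train, test = plan.folds[0]
        assert sorted(train.tolist()) == list(range(0, 16)) + list(range(20, 36))
        assert sorted(test.tolist()) == list(range(16, 20)) + list(range(36, 40))
        assert len(train) == 32 and len(test) == 8

    def test_personalized_window_parameter_errors(self):
        with pytest.raises(ParameterError):
            build_personalized_windows(make_dummy_pairs(10), window=20)
        with pytest.raises(ParameterError):
            build_personalized_windows(make_dummy_pairs(40), window=4)

    def test_loso_folds(self):
        pairs = []
        for s in "ABCDE":
            pairs += make_dummy_pairs(10, s)
        plan = build_loso(pairs)
        assert len(plan.folds) == 5
        subj = np.array([p.subject_id for p in pairs])
        tested = []
        for train, test in plan.folds:
            assert set(subj[train]).isdisjoint(set(subj[test]))
            assert len(set(subj[test])) == 1
            tested += test.tolist()
        assert sorted(tested) == list(range(50))  # each cycle tested exactly once

    def test_loso_single_subject_rejected(self):
        with pytest.raises(ParameterError):
            build_loso(make_dummy_pairs(10, "only"))


class TestRunScheme:
    def test_high_fidelity_on_clean_record(self, clean_sim):
        ec = ExperimentConfig()
        ec.segmentation["mode"] = "semantic"
        pairs = segment_record(clean_sim.record, ec)
        plan = build_personalized_windows(pairs)
        result = run_scheme(plan, pairs, PipelineParams())
        assert result.summary()["mean_rho"] >= 0.99

    def test_deterministic(self, clean_sim):
        ec = ExperimentConfig()
        pairs = segment_record(clean_sim.record, ec)
        plan = build_general_cv(pairs, k=5)
        r1 = run_scheme(plan, pairs, PipelineParams())
        r2 = run_scheme(plan, pairs, PipelineParams())
        assert r1.per_cycle.equals(r2.per_cycle)

    def test_aggregates_recomputable_from_per_cycle(self, clean_sim):
        ec = ExperimentConfig()
        pairs = segment_record(clean_sim.record, ec)
        plan = build_general_cv(pairs, k=5)
        result = run_scheme(plan, pairs, PipelineParams())
        s = result.summary()
        df = result.per_cycle
        assert s["mean_rho"] == pytest.approx(np.nanmean(df["rho"]))
        assert s["mean_r_delay_s"] == pytest.approx(np.nanmean(df["r_delay_s"]))
        assert s["n_cycles"] == len(df)


class TestConcatCorrelation:
    def test_perfect_direct_reconstructions_tile(self, clean_sim):
        ec = ExperimentConfig()
        ec.segmentation["mode"] = "direct"
        ec.smooth["enabled"] = False  # compare against the raw record
        pairs = segment_record(clean_sim.record, ec)
        # use the normalized ground-truth cycles as "reconstructions"
        recons = [normalize_pair(p)[1].values for p in pairs]
        out = concat_correlation(pairs, recons, clean_sim.record, ks=[1, 4, 8])
        for k in (1, 4, 8):
            assert np.median(out[k]) > 0.99

    def test_semantic_k1_close_to_per_cycle_rho(self, clean_sim):
        ec = ExperimentConfig()
        ec.segmentation["mode"] = "semantic"
        ec.smooth["enabled"] = False
        pairs = segment_record(clean_sim.record, ec)
        recons = [normalize_pair(p)[1].values for p in pairs]
        out = concat_correlation(pairs, recons, clean_sim.record, ks=[1], durations="cycle")
        assert np.median(out[1]) > 0.95

    def test_insufficient_cycles_rejected(self, clean_sim):
        ec = ExperimentConfig()
        pairs = segment_record(clean_sim.record, ec)[:4]
        recons = [normalize_pair(p)[1].values for p in pairs]
        with pytest.raises(ParameterError):
            concat_correlation(pairs, recons, clean_sim.record, ks=[8])
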