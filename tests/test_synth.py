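"""Generator calibration against the published dataset statistics and
structural invariants of the synthetic recordings."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from forcetrace import features, synth
from forcetrace.core import TASKS
from forcetrace.synth import DEFAULT_CONFIG, SkillEffect, SynthConfig


class TestSegmentDurations:
    def test_coagulation_moments_match_published_values(self):
        rng = np.random.default_rng(1)
        d = synth.sample_segment_duration("Coagulation", 50_000, rng)
        assert d.mean() == pytest.approx(12.1, rel=0.02)
        assert d.std() == pytest.approx(7.2, rel=0.02)

    def test_noncoagulation_mean_reflects_58pct_gap(self):
        rng = np.random.default_rng(1)
        d = synth.sample_segment_duration("Pulling", 50_000, rng)
        assert d.mean() == pytest.approx(12.1 / 1.58, rel=0.02)

    def test_zero_sd_degenerates_to_constant(self):
        cfg = dataclasses.replace(
            DEFAULT_CONFIG,
            duration_params={**DEFAULT_CONFIG.duration_params,
                             "Retracting": (9.0, 0.0)})
        d = synth.sample_segment_duration("Retracting", 100,
                                          np.random.default_rng(0), cfg)
        assert np.all(d == 9.0)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="unknown task"):
            synth.sample_segment_duration("Suturing", 10,
                                          np.random.default_rng(0))


class TestWaveforms:
    def test_noise_free_coagulation_plateau_and_boundaries(self):
        cfg = dataclasses.replace(DEFAULT_CONFIG, prong_correlation=1.0,
                                  tremor_amp=0.0, waveform_jitter=0.0)
        trace = synth.synth_task_waveform("Coagulation", 400, 1.0,
                                          np.random.default_rng(0), cfg)
        assert trace.max() == pytest.approx(1.0, abs=1e-9)
        assert np.median(trace[0]) == pytest.approx(1.0, abs=1e-6)
        assert trace[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert trace[0, -1] == pytest.approx(0.0, abs=0.05)

    def test_full_prong_correlation_gives_identical_channels(self):
        cfg = dataclasses.replace(DEFAULT_CONFIG, prong_correlation=1.0)
        trace = synth.synth_task_waveform("Pulling", 300, 1.2,
                                          np.random.default_rng(2), cfg)
        np.testing.assert_array_equal(trace[0], trace[1])

    def test_prong_correlation_is_calibrated(self):
        rng = np.random.default_rng(4)
        trace = synth.synth_task_waveform("Coagulation", 4000, 1.0, rng)
        r = np.corrcoef(trace[0], trace[1])[0, 1]
        assert r == pytest.approx(DEFAULT_CONFIG.prong_correlation, abs=0.1)

    def test_dissecting_is_spikier_than_retracting(self):
        rng = np.random.default_rng(3)
        spiky = synth.synth_task_waveform("Dissecting", 300, 1.0, rng)
        rng = np.random.default_rng(3)
        calm = synth.synth_task_waveform("Retracting", 300, 1.0, rng)
        assert np.diff(spiky[0]).var() > np.diff(calm[0]).var()

    @pytest.mark.parametrize("task", TASKS)
    def test_forces_nonnegative(self, task):
        trace = synth.synth_task_waveform(task, 200, 1.5,
                                          np.random.default_rng(5))
        assert trace.min() >= 0.0

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            synth.synth_task_waveform("Pulling", 10, 1.0,
                                      np.random.default_rng(0))


class TestSkillEffects:
    def test_expert_defaults_are_identity(self):
        trace = synth.synth_task_waveform("Coagulation", 200, 1.0,
                                          np.random.default_rng(0))
        out = synth.apply_skill_effects(trace, "Expert", SkillEffect(),
                                        np.random.default_rng(1))
        np.testing.assert_array_equal(out, trace)

    def test_neutral_novice_effects_are_identity(self):
        trace = synth.synth_task_waveform("Pulling", 200, 1.0,
                                          np.random.default_rng(0))
        out = synth.apply_skill_effects(
            trace, "Novice", SkillEffect(1.0, 0.0, 0.0),
            np.random.default_rng(1))
        np.testing.assert_array_equal(out, trace)

    def test_novice_increases_variability_but_not_duration(self):
        trace = synth.synth_task_waveform("Coagulation", 300, 1.0,
                                          np.random.default_rng(5))
        novice = synth.apply_skill_effects(
            trace, "Novice", DEFAULT_CONFIG.skill_effects["Novice"],
            np.random.default_rng(5))
        assert novice.shape == trace.shape          # duration untouched
        assert novice.std() > trace.std()


class TestRecordings:
    def test_recording_is_reproducible_per_seed(self, default_config):
        rec1, gt1 = synth.generate_recording(default_config, seed=7)
        rec2, gt2 = synth.generate_recording(default_config, seed=7)
        np.testing.assert_array_equal(rec1.left, rec2.left)
        np.testing.assert_array_equal(rec1.right, rec2.right)
        np.testing.assert_array_equal(rec1.labels, rec2.labels)
        assert len(gt1.segments) == len(gt2.segments)

    def test_zero_off_noise_gives_exact_zero_idle_force(self):
        cfg = dataclasses.replace(DEFAULT_CONFIG, off_noise_sd=0.0)
        rec, gt = synth.generate_recording(cfg, seed=3)
        off = ~gt.point_labels
        assert np.all(rec.left[off] == 0.0)
        assert np.all(rec.right[off] == 0.0)

    def test_ground_truth_invariants_hold(self, default_config):
        _, gt = synth.generate_recording(default_config, seed=11)
        gt.validate()       # raises on any violation
        starts = [s.start for s in gt.segments]
        assert starts == sorted(starts)

    def test_too_short_recording_rejected(self):
        cfg = dataclasses.replace(DEFAULT_CONFIG, recording_minutes=0.01)
        with pytest.raises(ValueError, match="too short"):
            synth.generate_recording(cfg, seed=0)

    def test_task_mix_respected_in_long_recording(self):
        cfg = dataclasses.replace(DEFAULT_CONFIG, recording_minutes=60.0)
        _, gt = synth.generate_recording(cfg, seed=2)
        tasks = [s.task for s in gt.segments]
        frac = tasks.count("Coagulation") / len(tasks)
        p = DEFAULT_CONFIG.task_mix["Coagulation"]
        # three binomial sigmas
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / len(tasks))


class TestDatasets:
    def test_manifest_counts_sum(self, small_dataset):
        segments, manifest = small_dataset
        assert manifest["n_segments"] == 300
        assert sum(manifest["class_counts"]["task"].values()) == 300
        assert sum(manifest["class_counts"]["skill"].values()) == 300

    def test_skill_labels_balanced_by_construction(self, default_config):
        segments, manifest = synth.generate_dataset(default_config, 2001,
                                                    seed=9)
        counts = manifest["class_counts"]["skill"]
        assert abs(counts["Novice"] - counts["Expert"]) <= 1

    def test_coagulation_count_matches_mix_at_published_scale(self,
                                                              default_config):
        segments, manifest = synth.generate_dataset(default_config, 2085,
                                                    seed=4)
        n_coag = manifest["class_counts"]["task"]["Coagulation"]
        p = default_config.task_mix["Coagulation"]
        sigma = np.sqrt(2085 * p * (1 - p))
        assert abs(n_coag - 2085 * p) < 3 * sigma      # 1170 expected

    def test_dataset_determinism(self, default_config):
        a, _ = synth.generate_dataset(default_config, 25, seed=5)
        b, _ = synth.generate_dataset(default_config, 25, seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.left, sb.left)
            assert sa.task == sb.task and sa.skill == sb.skill


class TestFeatureStructure:
    """Sign-level feature structure the generator must reproduce."""

    @pytest.fixture(scope="class")
    @staticmethod
    def feature_table(default_config):
        segments, _ = synth.generate_dataset(default_config, 2000, seed=42)
        table = features.feature_matrix(segments)
        return table

    def test_duration_force_positively_skewed(self, feature_table):
        assert stats.skew(feature_table["Duration Force"]) > 0.5

    def test_range_force_approximately_symmetric(self, feature_table):
        assert abs(stats.skew(feature_table["Range Force"])) < 0.5

    def test_entropy_anticorrelates_with_range(self, feature_table):
        r = np.corrcoef(feature_table["Entropy"],
                        feature_table["Range Force"])[0, 1]
        assert r < 0


class TestConfigValidation:
    def test_task_mix_must_sum_to_one(self):
        mix = dict(DEFAULT_CONFIG.task_mix)
        mix["Coagulation"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            SynthConfig(task_mix=mix)

    def test_negative_duration_rejected(self):
        params = dict(DEFAULT_CONFIG.duration_params)
        params["Pulling"] = (-1.0, 2.0)
        with pytest.raises(ValueError):
            SynthConfig(duration_params=params)

    def test_config_hash_stable(self):
        assert SynthConfig().hash() == SynthConfig().hash()
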