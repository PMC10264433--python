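"""Metric definitions against hand computations and brute-force
concordance/ANOVA oracles."""
import numpy as np
import pandas as pd
import pytest

from forcetrace.evalreport import (compute_metrics, crossvalidate,
                                   feature_anova, gauge_report,
                                   pointwise_weighted_f1)

CLASSES = ("OFF", "ON")


def _probs(pred_on):
    p = np.where(pred_on, 0.9, 0.1)
    return np.column_stack([1 - p, p])


class TestComputeMetrics:
    def test_hand_computed_confusion(self):
        # 10 positives: 7 predicted ON; 10 negatives: 8 predicted OFF
        y = np.array(["ON"] * 10 + ["OFF"] * 10)
        pred_on = np.array([True] * 7 + [False] * 3 + [False] * 8 + [True] * 2)
        rep = compute_metrics(y, _probs(pred_on), CLASSES, positive="ON")
        assert rep.sensitivity == pytest.approx(0.7)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.75)
        assert np.array(rep.confusion).sum() == 20

    def test_perfect_predictions(self):
        y = np.array(["ON", "OFF"] * 10)
        rep = compute_metrics(y, _probs(y == "ON"), CLASSES, positive="ON")
        assert rep.accuracy == 1.0
        assert rep.weighted_f1 == 1.0
        assert rep.macro_auc == 1.0

    def test_uninformative_probabilities_give_auc_half(self):
        y = np.array(["ON", "OFF"] * 20)
        probs = np.full((40, 2), 0.5)
        rep = compute_metrics(y, probs, CLASSES, positive="ON")
        assert rep.macro_auc == pytest.approx(0.5)

    def test_weighted_f1_recomputed_from_confusion(self):
        rng = np.random.default_rng(0)
        y = rng.choice(CLASSES, 200, p=[0.3, 0.7])
        pred_on = rng.random(200) > 0.4
        rep = compute_metrics(y, _probs(pred_on), CLASSES, positive="ON")
        cm = np.array(rep.confusion)        # rows = true, cols = predicted
        f1s, supports = [], []
        for k in range(2):
            tp = cm[k, k]
            prec = tp / cm[:, k].sum() if cm[:, k].sum() else 0.0
            rec = tp / cm[k, :].sum() if cm[k, :].sum() else 0.0
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
            supports.append(cm[k, :].sum())
        expected = np.average(f1s, weights=supports)
        assert rep.weighted_f1 == pytest.approx(expected, abs=1e-9)

    def test_single_class_labels_degrade_gracefully(self):
        y = np.array(["ON"] * 10)
        rep = compute_metrics(y, _probs(np.ones(10, bool)), CLASSES,
                              positive="ON")
        assert rep.macro_auc is None
        assert rep.accuracy == 1.0

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compute_metrics(np.array(["ON", "OFF"]),
                            np.array([[0.9, 0.9], [0.1, 0.1]]), CLASSES)


def _auc_concordance(y, scores):
    """Exhaustive pairwise Mann-Whitney AUC; ties count one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUCOracle:
    @pytest.mark.parametrize("n,tie_fraction", [(50, 0.0), (120, 0.3),
                                                (200, 0.8)])
    def test_matches_pairwise_concordance(self, n, tie_fraction):
        rng = np.random.default_rng(n)
        y = (rng.random(n) > 0.5).astype(int)
        scores = rng.random(n)
        ties = rng.random(n) < tie_fraction
        scores[ties] = np.round(scores[ties], 1)     # force ties
        labels = np.where(y == 1, "ON", "OFF")
        probs = np.column_stack([1 - scores, scores])
        rep = compute_metrics(labels, probs, CLASSES, positive="ON",
                              curves=False)
        assert rep.macro_auc == pytest.approx(_auc_concordance(y, scores),
                                              abs=1e-9)


class TestPointwiseF1:
    def test_perfect_mask(self):
        mask = np.array([0, 1, 1, 0, 1], dtype=bool)
        assert pointwise_weighted_f1(mask, mask.astype(float)) == 1.0


class _ConstantModel:
    def fit(self, X, y):
        self.label = "A"
        return self

    def predict_proba(self, X):
        return np.tile([0.9, 0.1], (len(X), 1))


class TestCrossValidate:
    def test_constant_model_on_balanced_data(self):
        X = np.zeros((100, 2))
        y = np.array(["A", "B"] * 50)
        out = crossvalidate(_ConstantModel, X, y, k=5, seed=0)
        assert out["cv_mean_accuracy"] == pytest.approx(0.5)
        assert out["cv_sd_accuracy"] == pytest.approx(0.0, abs=1e-12)

    def test_fold_sizes_and_cover(self):
        X = np.arange(103)[:, None].astype(float)
        y = np.array(["A", "B"] * 51 + ["A"])
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        sizes = [len(test) for _, test in skf.split(X, y)]
        assert max(sizes) - min(sizes) <= 1
        all_test = np.concatenate([test for _, test in skf.split(X, y)])
        assert sorted(all_test.tolist()) == list(range(103))

    def test_class_smaller_than_k_rejected(self):
        X = np.zeros((10, 1))
        y = np.array(["A"] * 8 + ["B"] * 2)
        with pytest.raises(ValueError, match="fewer"):
            crossvalidate(_ConstantModel, X, y, k=5, seed=0)


class TestFeatureAnova:
    def test_no_effect_gives_large_p(self):
        tasks = np.repeat(["Coagulation", "Pulling"], 30)
        skills = np.tile(np.repeat(["Expert", "Novice"], 15), 2)
        values = np.tile(np.arange(15.0), 4)      # identical per cell
        out = feature_anova(values, tasks, skills)
        assert out["p_task"] > 0.9
        assert out["p_skill"] > 0.9

    def test_injected_task_effect_detected(self):
        rng = np.random.default_rng(0)
        tasks = np.repeat(["Coagulation", "Pulling"], 100)
        skills = np.tile(np.repeat(["Expert", "Novice"], 50), 2)
        values = rng.normal(0, 1, 200) + np.where(tasks == "Coagulation",
                                                  2.0, 0.0)
        out = feature_anova(values, tasks, skills)
        assert out["p_task"] < 0.001
        assert out["p_skill"] > 0.05

    def test_balanced_2x2_matches_hand_computation(self):
        # textbook additive two-way ANOVA on a balanced 2x2 layout
        values = np.array([3.0, 5.0, 4.0, 6.0,        # Coag/Expert
                           7.0, 9.0, 8.0, 10.0,       # Coag/Novice
                           2.0, 4.0, 3.0, 5.0,        # Pull/Expert
                           6.0, 8.0, 7.0, 9.0])       # Pull/Novice
        tasks = np.repeat(["Coagulation", "Pulling"], 8)
        skills = np.tile(np.repeat(["Expert", "Novice"], 4), 2)
        out = feature_anova(values, tasks, skills)
        grand = values.mean()
        ss_task = sum(8 * (values[tasks == t].mean() - grand) ** 2
                      for t in ("Coagulation", "Pulling"))
        ss_skill = sum(8 * (values[skills == s].mean() - grand) ** 2
                       for s in ("Expert", "Novice"))
        fitted = np.array([values[tasks == t].mean()
                           + values[skills == s].mean() - grand
                           for t, s in zip(tasks, skills)])
        ss_res = ((values - fitted) ** 2).sum()
        df_res = len(values) - 3
        assert out["F_task"] == pytest.approx(ss_task / (ss_res / df_res),
                                              rel=1e-9)
        assert out["F_skill"] == pytest.approx(ss_skill / (ss_res / df_res),
                                               rel=1e-9)

    def test_sparse_cell_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            feature_anova([1.0, 2.0, 3.0, 4.0],
                          ["Coagulation", "Coagulation", "Pulling", "Pulling"],
                          ["Expert", "Novice", "Expert", "Novice"])


class TestGaugeReport:
    def _table(self, duration, rng_force=1.0, sd=0.3, entropy=0.5, n=10):
        return pd.DataFrame({
            "Duration Force": np.full(n, duration),
            "Range Force": np.full(n, rng_force),
            "SD Force": np.full(n, sd),
            "Entropy": np.full(n, entropy),
        })

    def test_identical_tables_give_zero_deltas(self):
        t = self._table(12.0)
        rep = gauge_report(t, t)
        assert all(m["delta"] == 0.0 for m in rep.metrics.values())

    def test_signed_duration_delta(self):
        rep = gauge_report(self._table(14.0), self._table(11.81))
        assert rep.metrics["Average Force Duration"]["delta"] == \
            pytest.approx(2.19)

    def test_expert_sd_nonnegative(self):
        rng = np.random.default_rng(0)
        expert = self._table(12.0)
        expert["Duration Force"] = rng.normal(12, 3, len(expert))
        rep = gauge_report(self._table(13.0), expert)
        assert all(m["expert_sd"] >= 0 for m in rep.metrics.values())

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            gauge_report(self._table(12.0).drop(columns=["Entropy"]),
                         self._table(12.0))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gauge_report(self._table(12.0).iloc[:0], self._table(12.0))
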