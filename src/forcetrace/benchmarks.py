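"""Standard synthetic benchmarks for the segmentation and recognition
models.

These assemble the full desk-scale pipeline — generate data, balance,
window, standardize (training statistics only), augment with the
feature channel, train, evaluate — at sizes small enough for a single
CPU while preserving the pipeline's structure. They are used by the
test-suite, the reproduction script and the command-line runner alike.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import evalreport, features, preprocess, recog, segmodel, synth
from .preprocess import Standardizer, one_hot

TASK_CLASSES = ("non-Coagulation", "Coagulation")


# ---------------------------------------------------------------------------
# generator calibration measurements

def coagulation_duration_moments(n: int = 50_000, seed: int = 1,
                                 config: synth.SynthConfig | None = None,
                                 ) -> tuple[float, float]:
    """Sample mean and SD (s) of ``n`` Coagulation duration draws."""
    cfg = config or synth.DEFAULT_CONFIG
    rng = np.random.default_rng(seed)
    d = synth.sample_segment_duration("Coagulation", n, rng, cfg)
    return float(d.mean()), float(d.std())


def coagulation_excess_pct(n_segments: int = 10_000, seed: int = 4,
                           config: synth.SynthConfig | None = None) -> float:
    """Relative excess (%) of mean Coagulation duration over the mean
    duration of all other tasks, measured on a generated dataset."""
    cfg = config or synth.DEFAULT_CONFIG
    segments, _ = synth.generate_dataset(cfg, n_segments, seed=seed)
    coag = [s.duration_s for s in segments if s.task == "Coagulation"]
    other = [s.duration_s for s in segments if s.task != "Coagulation"]
    return 100.0 * (np.mean(coag) - np.mean(other)) / np.mean(other)


def skill_duration_gap_pct(n_pairs: int = 5_000, seed: int = 6,
                           config: synth.SynthConfig | None = None) -> float:
    """Absolute % difference of mean Coagulation duration, Novice vs Expert.

    Paired (common-random-numbers) design: each duration draw is rendered
    once per skill through the full segment pipeline, so the measured gap
    isolates the skill-effect pathway from duration sampling noise. Any
    skill effect that altered segment length would register directly.
    """
    cfg = config or synth.DEFAULT_CONFIG
    rng = np.random.default_rng(seed)
    durations = synth.sample_segment_duration("Coagulation", n_pairs, rng, cfg)
    means = {}
    for skill in ("Expert", "Novice"):
        srng = np.random.default_rng(seed + (1 if skill == "Novice" else 2))
        realized = [synth.make_segment("Coagulation", skill, srng, cfg,
                                       duration_s=d).duration_s
                    for d in durations]
        means[skill] = float(np.mean(realized))
    return 100.0 * abs(means["Novice"] - means["Expert"]) / means["Expert"]


@dataclass
class SegmentationBenchmark:
    train: tuple
    val: tuple
    test: tuple
    standardizer: Standardizer


def segmentation_benchmark(n_windows: int = 400, seed: int = 7,
                           config: synth.SynthConfig | None = None,
                           L: int = 224) -> SegmentationBenchmark:
    """Labeled, idle-balanced, standardized 224-point windows."""
    cfg = config or replace(synth.DEFAULT_CONFIG, recording_minutes=30.0)
    windows, labels = [], []
    sub = 0
    while sum(len(w) for w in windows) < n_windows:
        rec, _ = synth.generate_recording(cfg, seed=seed * 1000 + sub)
        rec = preprocess.balance_idle(rec, max_off_run=L)
        w, lab = preprocess.make_windows(rec, L=L, stride=L)
        windows.append(w)
        labels.append(lab)
        sub += 1
    X = np.concatenate(windows)[:n_windows]
    y = np.concatenate(labels)[:n_windows]
    idx_train, idx_val, idx_test = preprocess.split_nested(
        list(range(len(X))), seed=seed)
    std = Standardizer.fit(
        X[idx_train].transpose(1, 0, 2).reshape(2, -1))
    tf = lambda idx: ((X[idx] - std.mean[None, :, None])
                      / std.sd[None, :, None], y[idx])
    return SegmentationBenchmark(train=tf(idx_train), val=tf(idx_val),
                                 test=tf(idx_test), standardizer=std)


def run_segmentation_benchmark(n_windows: int = 400, seed: int = 7,
                               max_epochs: int = 30) -> dict:
    """Train the T-U-Net at desk scale and score the held-out windows.

    Mini-batches of 16 keep the optimizer step count at this reduced
    dataset size comparable to a full-scale run; filter size, learning
    rate and window length keep their full-scale values.
    """
    bench = segmentation_benchmark(n_windows=n_windows, seed=seed)
    cfg = segmodel.TUNetConfig(max_epochs=max_epochs, patience=5, seed=seed,
                               batch_size=16)
    model = segmodel.build_tunet(cfg)
    history = segmodel.train_segmenter(model, bench.train, bench.val, cfg)
    Xt, yt = bench.test
    probs = model.predict_proba(np.asarray(Xt, dtype=np.float32))
    f1 = evalreport.pointwise_weighted_f1(yt, probs)
    return {"weighted_f1": f1, "history": history.to_dict(),
            "n_test_windows": len(Xt)}


@dataclass
class TaskBenchmark:
    train: tuple           # (windows, onehot, labels)
    val: tuple
    test: tuple
    feature_table: dict    # split -> engineered feature matrix (subset)


def task_benchmark(n_segments: int = 1000, seed: int = 11,
                   config: synth.SynthConfig | None = None, L: int = 200,
                   coag_fraction: float = 0.5,
                   feature_subset: tuple = features.SUBSET1,
                   augment: bool = True) -> TaskBenchmark:
    """Coagulation vs non-Coagulation windows with the feature channel.

    Follows the pipeline order: subsample the over-represented
    Coagulation class, split 64/16/20, window to ``L`` points,
    standardize forces and features on the training split only, then
    append the engineered-feature channel (cubic spline spread).
    """
    cfg = config or synth.DEFAULT_CONFIG
    segments, _ = synth.generate_dataset(cfg, n_segments, seed=seed)
    segments = preprocess.subsample_class(segments, "Coagulation",
                                          coag_fraction, seed=seed)
    train_segs, val_segs, test_segs = preprocess.split_nested(segments,
                                                              seed=seed)
    feat_cols = list(feature_subset)

    def windows_of(segs):
        return np.stack([preprocess.segment_to_window(s, L=L) for s in segs])

    def labels_of(segs):
        return np.array(["Coagulation" if s.task == "Coagulation"
                         else "non-Coagulation" for s in segs])

    Xtr = windows_of(train_segs)
    std = Standardizer.fit(Xtr.transpose(1, 0, 2).reshape(2, -1))
    feats = {name: features.feature_matrix(segs)[feat_cols].to_numpy()
             for name, segs in (("train", train_segs), ("val", val_segs),
                                ("test", test_segs))}
    fmean = feats["train"].mean(axis=0)
    fsd = np.where(feats["train"].std(axis=0) == 0, 1.0,
                   feats["train"].std(axis=0))

    def assemble(segs, name):
        X = windows_of(segs)
        X = (X - std.mean[None, :, None]) / std.sd[None, :, None]
        if augment:
            fz = (feats[name] - fmean) / fsd
            chan = np.stack([preprocess.feature_channel(row, L=L, order=3)
                             for row in fz])
            X = np.concatenate([X, chan[:, None, :]], axis=1)
        labels = labels_of(segs)
        return X.astype(np.float32), one_hot(labels, TASK_CLASSES), labels

    return TaskBenchmark(train=assemble(train_segs, "train"),
                         val=assemble(val_segs, "val"),
                         test=assemble(test_segs, "test"),
                         feature_table=feats)


def run_task_benchmark(n_segments: int = 1000, seed: int = 11,
                       max_epochs: int = 30, depth: int = 6,
                       bench: TaskBenchmark | None = None) -> dict:
    """Train FTFIT on the task benchmark and report held-out metrics."""
    if bench is None:
        bench = task_benchmark(n_segments=n_segments, seed=seed)
    Xtr, ytr, _ = bench.train
    cfg = recog.FTFITConfig(in_channels=Xtr.shape[1], depth=depth,
                            max_epochs=max_epochs, patience=5, seed=seed)
    model = recog.build_ftfit(cfg)
    history = recog.train_classifier(model, (Xtr, ytr),
                                     (bench.val[0], bench.val[1]), cfg)
    Xt, _, labels_t = bench.test
    probs = model.predict_proba(Xt)
    report = evalreport.compute_metrics(labels_t, probs, TASK_CLASSES,
                                        positive="Coagulation", curves=False)
    return {"macro_auc": report.macro_auc, "weighted_f1": report.weighted_f1,
            "accuracy": report.accuracy, "history": history.to_dict(),
            "report": report.to_dict(), "n_test": len(Xt)}


def run_lstm_task_benchmark(bench: TaskBenchmark, seed: int = 11,
                            max_epochs: int = 30) -> dict:
    """LSTM baseline on the same task benchmark windows."""
    Xtr, ytr, _ = bench.train
    cfg = recog.LSTMConfig(in_channels=Xtr.shape[1], max_epochs=max_epochs,
                           patience=5, seed=seed)
    model = recog.build_lstm(cfg)
    history = recog.train_classifier(model, (Xtr, ytr),
                                     (bench.val[0], bench.val[1]), cfg)
    Xt, _, labels_t = bench.test
    probs = model.predict_proba(Xt)
    report = evalreport.compute_metrics(labels_t, probs, TASK_CLASSES,
                                        positive="Coagulation", curves=False)
    return {"macro_auc": report.macro_auc, "weighted_f1": report.weighted_f1,
            "accuracy": report.accuracy, "history": history.to_dict()}
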