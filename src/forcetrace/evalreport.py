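"""Metrics, cross-validation, feature statistics and the expert-comparison
gauge report.

AUC follows the trapezoidal ROC / pairwise-concordance convention (score
ties count one half), so it agrees exactly with a Mann-Whitney
computation. Weighted F1 is the support-weighted mean of per-class F1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             f1_score, precision_recall_curve, roc_auc_score,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold

from .preprocess import one_hot


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    per_class_f1: dict
    weighted_f1: float
    macro_auc: float | None
    average_precision: float | None
    confusion: list
    roc_points: dict | None = None
    pr_points: dict | None = None
    cv_mean_accuracy: float | None = None
    cv_sd_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compute_metrics(y_true, probabilities: np.ndarray, classes,
                    positive: str | int | None = None,
                    curves: bool = True) -> EvalReport:
    """Metric bundle from class probabilities.

    ``probabilities`` has one column per entry of ``classes`` (rows sum
    to 1). Hard labels threshold the positive-class probability at 0.5
    for binary problems. With a single observed class, AUC and average
    precision are reported as None (labeled degenerate) while the other
    metrics are still computed.
    """
    classes = list(classes)
    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape[1] != len(classes):
        raise ValueError("probability columns must match classes")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    positive = classes[-1] if positive is None else positive
    pos_idx = classes.index(positive)
    if len(classes) == 2:
        y_pred = np.where(probabilities[:, pos_idx] >= 0.5, classes[pos_idx],
                          classes[1 - pos_idx])
    else:
        y_pred = np.asarray(classes)[probabilities.argmax(axis=1)]
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = float((y_true == y_pred).mean())
    pos_mask = y_true == positive
    sensitivity = float((y_pred[pos_mask] == positive).mean()) if pos_mask.any() else 0.0
    neg_mask = ~pos_mask
    specificity = float((y_pred[neg_mask] != positive).mean()) if neg_mask.any() else 0.0
    per_class = f1_score(y_true, y_pred, labels=classes, average=None,
                         zero_division=0)
    weighted = float(f1_score(y_true, y_pred, labels=classes,
                              average="weighted", zero_division=0))
    single_class = len(np.unique(y_true)) < 2
    macro_auc = ap = None
    roc_points = pr_points = None
    if not single_class:
        y_bin = one_hot(y_true, classes)
        macro_auc = float(np.mean([
            roc_auc_score(y_bin[:, k], probabilities[:, k])
            for k in range(len(classes))]))
        ap = float(average_precision_score(pos_mask.astype(int),
                                           probabilities[:, pos_idx]))
        if curves:
            fpr, tpr, _ = roc_curve(pos_mask.astype(int),
                                    probabilities[:, pos_idx])
            prec, rec, _ = precision_recall_curve(pos_mask.astype(int),
                                                  probabilities[:, pos_idx])
            roc_points = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
            pr_points = {"precision": prec.tolist(), "recall": rec.tolist()}
    return EvalReport(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        per_class_f1={c: float(f) for c, f in zip(classes, per_class)},
        weighted_f1=weighted, macro_auc=macro_auc, average_precision=ap,
        confusion=cm.tolist(), roc_points=roc_points, pr_points=pr_points)


def pointwise_weighted_f1(y_true_mask: np.ndarray, probs_on: np.ndarray,
                          threshold: float = 0.5) -> float:
    """Weighted F1 of per-sample ON/OFF decisions."""
    y_true = np.where(np.asarray(y_true_mask).ravel(), "ON", "OFF")
    y_pred = np.where(np.asarray(probs_on).ravel() >= threshold, "ON", "OFF")
    return float(f1_score(y_true, y_pred, labels=["OFF", "ON"],
                          average="weighted", zero_division=0))


def crossvalidate(builder, X, y, k: int = 5, seed: int = 0) -> dict:
    """Stratified k-fold cross-validation of accuracy.

    ``builder()`` must return a fresh object with ``fit(X, y)`` and
    ``predict_proba(X)``. Every sample is tested exactly once.
    """
    y = np.asarray(y)
    X = np.asarray(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members "
                         f"than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    fold_reports = []
    classes = list(pd.unique(y))
    for train_idx, test_idx in skf.split(X, y):
        model = builder()
        model.fit(X[train_idx], y[train_idx])
        probs = model.predict_proba(X[test_idx])
        rep = compute_metrics(y[test_idx], probs, classes, curves=False)
        fold_acc.append(rep.accuracy)
        fold_reports.append(rep.to_dict())
    return {
        "cv_mean_accuracy": float(np.mean(fold_acc)),
        "cv_sd_accuracy": float(np.std(fold_acc, ddof=1)),
        "fold_accuracy": fold_acc,
        "fold_reports": fold_reports,
    }


def feature_anova(values, task_labels, skill_labels) -> dict:
    """Additive two-way ANOVA of one feature on task and skill factors.

    Returns F statistics and p-values for each factor. Requires at least
    two levels per factor and three observations per factor-level cell.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "task": np.asarray(task_labels),
                       "skill": np.asarray(skill_labels)})
    for col in ("task", "skill"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    cell_counts = df.groupby(["task", "skill"], observed=True).size()
    if (cell_counts < 3).any():
        bad = cell_counts[cell_counts < 3].index[0]
        raise ValueError(f"cell {bad} has fewer than 3 observations")
    model = smf.ols("value ~ C(task) + C(skill)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "F_task": float(table.loc["C(task)", "F"]),
        "p_task": float(table.loc["C(task)", "PR(>F)"]),
        "F_skill": float(table.loc["C(skill)", "F"]),
        "p_skill": float(table.loc["C(skill)", "PR(>F)"]),
    }


#: Dashboard gauge metrics -> canonical feature columns.
GAUGE_METRICS = {
    "Average Force Duration": "Duration Force",
    "Range of Forces": "Range Force",
    "Force Variability": "SD Force",
    "Force Uncertainty": "Entropy",
}


@dataclass
class GaugeReport:
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"metrics": self.metrics}


def gauge_report(surgeon: pd.DataFrame, expert_reference: pd.DataFrame,
                 mapping: dict[str, str] | None = None) -> GaugeReport:
    """Surgeon-vs-expert comparison of the dashboard performance indices.

    For each gauge metric: the surgeon's mean, the expert reference mean
    and SD, and the signed delta (surgeon minus expert). Emitted as data
    (JSON-serializable), not a UI.
    """
    mapping = GAUGE_METRICS if mapping is None else mapping
    if len(surgeon) == 0 or len(expert_reference) == 0:
        raise ValueError("both feature tables must be non-empty")
    out = {}
    for metric, column in mapping.items():
        for name, table in (("surgeon", surgeon),
                            ("expert", expert_reference)):
            if column not in table.columns:
                raise ValueError(f"{name} table is missing column {column!r}")
        s_mean = float(surgeon[column].mean())
        e_mean = float(expert_reference[column].mean())
        e_sd = float(expert_reference[column].std(ddof=0))
        out[metric] = {
            "surgeon_mean": s_mean,
            "expert_mean": e_mean,
            "expert_sd": e_sd,
            "delta": s_mean - e_mean,
        }
    return GaugeReport(metrics=out)
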