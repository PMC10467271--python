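"""PSD vs non-PSD classification from the 79 network-AUC features.

Features are the AUCs of 9 global metrics plus 5 nodal metrics × 14
channels for one state. The classifier is a cost-sensitive support vector
machine (class weights inversely proportional to class frequency) on
principal components retaining a fixed fraction of training-fold variance,
evaluated by stratified 8-fold cross-validation repeated 10 times.
Standardization and the principal-component projection are fitted strictly
inside each training fold — no information from held-out subjects leaks
into the preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graphmetrics import GLOBAL_METRICS, MetricSet, NODAL_METRICS

N_CHANNELS_DEFAULT = 14


def feature_names(n_channels: int = N_CHANNELS_DEFAULT) -> list[str]:
    """Canonical feature order: 9 global AUCs, then nodal AUCs metric-major."""
    names = [f"global.{m}" for m in GLOBAL_METRICS]
    for m in NODAL_METRICS:
        names += [f"nodal.{m}.ch{c + 1:02d}" for c in range(n_channels)]
    return names


def assemble_features(
    metric_sets: dict[str, MetricSet] | list[MetricSet],
    state: str,
    impute: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the subjects × 79 feature table for one state.

    Missing values (e.g. assortativity or hierarchy undefined at some
    threshold, propagated to a NaN AUC) are imputed by the column median;
    the returned log names each imputed cell. Subjects lacking the requested
    state are excluded with a log entry.
    """
    if isinstance(metric_sets, dict):
        metric_sets = list(metric_sets.values())
    rows, index, log = [], [], []
    n_ch = None
    for ms in metric_sets:
        if ms.state != state:
            continue
        if n_ch is None:
            n_ch = len(ms.nodal_auc)
        vals = [ms.global_auc[m] for m in GLOBAL_METRICS]
        for m in NODAL_METRICS:
            vals.extend(ms.nodal_auc[m].tolist())
        rows.append(vals)
        index.append(ms.subject_id)
    if not rows:
        raise ValueError(f"no metric sets for state {state!r}")
    table = pd.DataFrame(rows, index=index, columns=feature_names(n_ch))
    if impute:
        for col in table.columns[table.isna().any()]:
            med = table[col].median()
            for sid in table.index[table[col].isna()]:
                log.append(f"imputed {col} for {sid} with column median {med:.6g}")
            table[col] = table[col].fillna(med)
    return table, log


@dataclass
class ClassificationReport:
    """Cross-validated accuracy of the cost-sensitive SVM."""

    fold_accuracies: np.ndarray     # (n_repeats, n_folds)
    repeat_accuracies: np.ndarray   # pooled correct/total per repeat
    mean_accuracy: float
    sd_accuracy: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "repeat_accuracies": self.repeat_accuracies.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "config": self.config,
        }


def _default_pipeline(variance_retained: float, cost_mode: str, kernel: str, c: float) -> Pipeline:
    class_weight = "balanced" if cost_mode == "balanced" else None
    return make_pipeline(
        StandardScaler(),
        PCA(n_components=variance_retained, svd_solver="full"),
        SVC(kernel=kernel, C=c, class_weight=class_weight),
    )


def fit_eval(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_folds: int = 8,
    n_repeats: int = 10,
    variance_retained: float = 0.95,
    cost_mode: str = "balanced",
    kernel: str = "linear",
    c: float = 1.0,
    seed: int = 0,
    pipeline_factory=None,
) -> ClassificationReport:
    """Repeated stratified k-fold evaluation of the cost-sensitive SVM.

    Per repeat, a fresh seeded stratified split is drawn; within each
    training fold the features are standardized, projected onto principal
    components retaining ``variance_retained`` of the variance, and a margin
    classifier with class-frequency-inverse costs is trained, then scored on
    the held-out fold. Accuracy per repeat is pooled correct/total; the
    report carries the mean ± SD over repeats and every fold accuracy.
    """
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2 or min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need two classes with >= 2 subjects each")
    if pipeline_factory is None:
        pipeline_factory = lambda: _default_pipeline(variance_retained, cost_mode, kernel, c)
    rng = np.random.default_rng(seed)
    fold_acc = np.zeros((n_repeats, n_folds))
    repeat_acc = np.zeros(n_repeats)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        correct = total = 0
        for f, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[tr])) < 2:  # cannot happen with stratified folds
                raise RuntimeError("single-class training fold")
            clf = pipeline_factory()
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            hits = int((pred == y[te]).sum())
            fold_acc[rep, f] = hits / len(te)
            correct += hits
            total += len(te)
        repeat_acc[rep] = correct / total
    return ClassificationReport(
        fold_accuracies=fold_acc,
        repeat_accuracies=repeat_acc,
        mean_accuracy=float(repeat_acc.mean()),
        sd_accuracy=float(repeat_acc.std(ddof=1)) if n_repeats > 1 else 0.0,
        config={
            "n_folds": n_folds, "n_repeats": n_repeats,
            "variance_retained": variance_retained, "cost_mode": cost_mode,
            "kernel": kernel, "C": c, "seed": seed,
        },
    )
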