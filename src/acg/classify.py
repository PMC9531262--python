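"""Diagnostic classification and evaluation.

Patient-days are labelled positive when ICDSC or SOFA reaches 3; a support
vector machine is assessed by stratified fivefold cross-validation
(grouped by patient by default, so no patient contributes to both a
training and a test fold), reporting accuracy, sensitivity and specificity
in percent plus the ROC curve of pooled decision values.  A second,
per-patient protocol trains on the first 10 enrolled patients and tests on
the last 10 at single-measurement granularity, issuing a correct / wrong /
undecided verdict per test patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import PatientRecord

__all__ = [
    "CVMetrics", "ROCCurve", "PatientVerdict",
    "label_positive", "confusion_metrics", "crossval_svm", "roc",
    "patient_split_classifier",
]

log = logging.getLogger(__name__)


@dataclass
class CVMetrics:
    per_fold: list[dict]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    k: int
    seed: int
    scores: np.ndarray | None = None   # pooled out-of-fold decision values
    labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k, "seed": self.seed,
            "mean_accuracy_pct": self.mean_accuracy,
            "mean_sensitivity_pct": self.mean_sensitivity,
            "mean_specificity_pct": self.mean_specificity,
            "per_fold": self.per_fold,
        }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class PatientVerdict:
    patient_id: str
    verdict: str                      # correct | wrong | undecided
    n_measurements: int
    n_correct: int
    cluster_agreement: float = float("nan")


def label_positive(record: PatientRecord, threshold: int = 3) -> bool:
    """Positive iff ICDSC or SOFA reaches the threshold (default 3)."""
    if record.sofa is None or record.icdsc is None:
        raise ValueError("record lacks SOFA or ICDSC")
    return record.icdsc >= threshold or record.sofa >= threshold


def confusion_metrics(predicted, truth) -> dict:
    """Accuracy/sensitivity/specificity (percent) from binary vectors.

    Ratios with a zero denominator (a class absent from ``truth``) are
    reported as None and excluded from any averaging by the caller.
    """
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int(np.sum(p & t)); tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t)); fn = int(np.sum(~p & t))
    n = p.size
    out = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": 100.0 * (tp + tn) / n if n else None,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else None,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else None,
    }
    if out["sensitivity"] is None or out["specificity"] is None:
        log.info("a class is absent; undefined rate reported as None")
    return out


def _svm(kernel: str, c: float) -> object:
    # balanced class weights: positive patient-days heavily outnumber negative
    # ones under the ICDSC-or-SOFA >= 3 rule, and an unweighted margin would
    # collapse to the majority class
    return make_pipeline(StandardScaler(),
                         SVC(kernel=kernel, C=c, class_weight="balanced"))


def crossval_svm(features: np.ndarray, labels: np.ndarray, k: int = 5,
                 seed: int = 0, groups: np.ndarray | None = None,
                 kernel: str = "linear", c: float = 1.0,
                 row_keys=None) -> CVMetrics:
    """Stratified k-fold SVM evaluation.

    With ``groups`` (patient ids) folds never split a patient across train
    and test.  ``row_keys`` (e.g. (patient_id, day) tuples) canonicalises
    the row order before splitting, making the metrics invariant to how the
    caller happened to order the rows.  Undefined per-fold rates
    (single-class test folds) are skipped in the fold averages.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=bool)
    if row_keys is not None:
        order = sorted(range(x.shape[0]), key=lambda i: tuple(row_keys[i]))
        x, y = x[order], y[order]
        if groups is not None:
            groups = np.asarray(groups)[order]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present overall")
    if x.shape[0] < k:
        raise ValueError("fewer rows than folds")

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(x, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(x, y)

    per_fold, scores, labs = [], np.full(x.shape[0], np.nan), y.copy()
    for train, test in splits:
        if len(np.unique(y[train])) < 2:
            log.warning("training fold with a single class; fold skipped")
            continue
        clf = _svm(kernel, c)
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        scores[test] = clf.decision_function(x[test])
        per_fold.append(confusion_metrics(pred, y[test]))

    def fold_mean(key: str) -> float:
        vals = [f[key] for f in per_fold if f[key] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    return CVMetrics(
        per_fold=per_fold,
        mean_accuracy=fold_mean("accuracy"),
        mean_sensitivity=fold_mean("sensitivity"),
        mean_specificity=fold_mean("specificity"),
        k=k, seed=seed, scores=scores, labels=labs,
    )


def roc(scores, labels) -> ROCCurve:
    """ROC curve over all distinct score thresholds; AUC by trapezoid rule."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def patient_split_classifier(
    features: np.ndarray,
    patient_ids: np.ndarray,
    labels: np.ndarray,
    enrollment_order: list[str],
    seed: int = 0,
    kernel: str = "linear",
    c: float = 1.0,
) -> list[PatientVerdict]:
    """Train on the first half of enrolled patients, verdict the second half.

    ``features`` holds one row per single measurement (e.g. the two
    GA-derived components); ``labels`` the measurement's patient-day label.
    K-means (k=2) on the training rows provides an unsupervised sanity
    grouping (its agreement with the labels is reported per patient); the
    SVM makes the predictions.  A test patient is ``correct`` when every
    one of its measurement predictions matches, ``wrong`` when none does,
    ``undecided`` otherwise.
    """
    x = np.asarray(features, dtype=float)
    pid = np.asarray(patient_ids)
    y = np.asarray(labels, dtype=bool)
    half = len(enrollment_order) // 2
    train_ids = set(enrollment_order[:half])
    test_ids = [p for p in enrollment_order[half:]]
    if half < 2 or len(test_ids) < 2:
        raise ValueError("need at least 2 patients per split")
    tr = np.isin(pid, sorted(train_ids))
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training split has a single class")

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x[tr])
    clusters = km.predict(x)
    # align cluster index to the majority class among training rows
    pos_rate = [np.mean(y[tr][km.labels_ == c0]) if np.any(km.labels_ == c0) else 0.0
                for c0 in (0, 1)]
    pos_cluster = int(np.argmax(pos_rate))

    clf = _svm(kernel, c)
    clf.fit(x[tr], y[tr])
    pred = clf.predict(x)

    verdicts: list[PatientVerdict] = []
    for p in test_ids:
        rows = pid == p
        if not np.any(rows):
            continue
        ok = pred[rows] == y[rows]
        if ok.all():
            verdict = "correct"
        elif not ok.any():
            verdict = "wrong"
        else:
            verdict = "undecided"
        agree = float(np.mean((clusters[rows] == pos_cluster) == y[rows]))
        verdicts.append(PatientVerdict(
            patient_id=str(p), verdict=verdict,
            n_measurements=int(rows.sum()), n_correct=int(ok.sum()),
            cluster_agreement=agree,
        ))
    return verdicts
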