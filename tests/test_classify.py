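"""Labeling rule, confusion metrics, cross-validated SVM, ROC, patient split."""

import numpy as np
import pytest
from scipy import stats

from acg import PatientRecord
from acg.classify import (
    confusion_metrics,
    crossval_svm,
    label_positive,
    patient_split_classifier,
    roc,
)


def record(sofa, icdsc, group="SG"):
    if group == "CG":
        icdsc = 0
    return PatientRecord(patient_id="P01", group=group, day=1, severity=0.5,
                         sofa=sofa, icdsc=icdsc, cam_icu=group == "SG" and icdsc >= 4,
                         lactate=1.0, pct=1.0, creatinine=80.0, bilirubin=10.0)


class TestLabeling:
    @pytest.mark.parametrize("sofa,icdsc,expected", [
        (0, 0, False),          # neither score elevated
        (3, 0, True),           # SOFA alone reaches the cut-off
        (2, 3, True),           # ICDSC alone reaches the cut-off
        (2, 2, False),
    ])
    def test_icdsc_or_sofa_threshold_three(self, sofa, icdsc, expected):
        assert label_positive(record(sofa, icdsc)) is expected

    def test_custom_threshold(self):
        assert label_positive(record(4, 0), threshold=5) is False


class TestConfusionMetrics:
    def test_perfect_and_inverted_predictions(self):
        t = [True, True, False, False]
        perfect = confusion_metrics(t, t)
        assert (perfect["accuracy"], perfect["sensitivity"], perfect["specificity"]) \
            == (100.0, 100.0, 100.0)
        inverted = confusion_metrics([not v for v in t], t)
        assert (inverted["accuracy"], inverted["sensitivity"], inverted["specificity"]) \
            == (0.0, 0.0, 0.0)

    def test_hand_counted_two_by_two(self):
        # truth (P,P,N,N), predicted (P,N,N,N): TP=1 FN=1 TN=2 FP=0
        m = confusion_metrics([True, False, False, False], [True, True, False, False])
        assert m["accuracy"] == 75.0
        assert m["sensitivity"] == 50.0
        assert m["specificity"] == 100.0

    def test_absent_class_reported_as_missing(self):
        m = confusion_metrics([True, True], [True, True])
        assert m["specificity"] is None and m["sensitivity"] == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([True], [True, False])

    def test_flipping_labels_never_improves_metrics(self):
        truth = np.array([True, True, True, False, False, False])
        pred = truth.copy()
        prev = confusion_metrics(pred, truth)
        for i in range(len(pred)):
            pred[i] = not pred[i]
            cur = confusion_metrics(pred, truth)
            for key in ("accuracy", "sensitivity", "specificity"):
                if prev[key] is not None and cur[key] is not None:
                    assert cur[key] <= prev[key] + 1e-9
            prev = cur


class TestCrossvalSVM:
    def test_well_separated_clouds_are_perfectly_classified(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-3, 0.5, (50, 2)), rng.normal(3, 0.5, (50, 2))])
        y = np.repeat([False, True], 50)
        cv = crossval_svm(x, y, k=5, seed=1)
        assert cv.mean_accuracy == 100.0
        assert cv.k == 5 and len(cv.per_fold) == 5

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        accs = []
        for seed in range(20):
            x = rng.standard_normal((200, 4))
            y = rng.permutation(np.repeat([False, True], 100))
            accs.append(crossval_svm(x, y, k=5, seed=seed).mean_accuracy)
        assert np.mean(accs) == pytest.approx(50.0, abs=10.0)

    def test_single_class_overall_rejected(self):
        with pytest.raises(ValueError):
            crossval_svm(np.zeros((10, 2)), np.ones(10, dtype=bool))

    def test_row_permutation_invariance_with_keys(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(-1, 1, (30, 2)), rng.normal(1, 1, (30, 2))])
        y = np.repeat([False, True], 30)
        keys = [(f"P{i:03d}", 1) for i in range(60)]
        base = crossval_svm(x, y, k=5, seed=3, row_keys=keys)
        perm = rng.permutation(60)
        shuffled = crossval_svm(x[perm], y[perm], k=5, seed=3,
                                row_keys=[keys[i] for i in perm])
        assert shuffled.mean_accuracy == base.mean_accuracy
        assert shuffled.mean_sensitivity == base.mean_sensitivity
        assert shuffled.mean_specificity == base.mean_specificity

    def test_grouped_folds_keep_patients_together(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 2))
        x[20:] += 3
        y = np.repeat([False, True], 20)
        groups = np.repeat([f"P{i}" for i in range(10)], 4)
        cv = crossval_svm(x, y, k=5, seed=0, groups=groups)
        assert np.isfinite(cv.mean_accuracy)


class TestROC:
    def test_perfect_and_reversed_ordering(self):
        y = np.repeat([False, True], 10)
        s = np.arange(20, dtype=float)
        assert roc(s, y).auc == pytest.approx(1.0)
        assert roc(-s, y).auc == pytest.approx(0.0)

    def test_random_scores_are_chance_level(self):
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(20):
            y = rng.random(1000) < 0.5
            s = rng.standard_normal(1000)
            aucs.append(roc(s, y).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        y = rng.random(100) < 0.4
        c = roc(rng.standard_normal(100), y)
        assert c.fpr[0] == 0.0 and c.tpr[0] == 0.0
        assert c.fpr[-1] == 1.0 and c.tpr[-1] == 1.0
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_auc_equals_normalised_mann_whitney_u(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n_pos, n_neg = rng.integers(5, 40, size=2)
            y = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            s = rng.standard_normal(n_pos + n_neg)
            u = stats.mannwhitneyu(s[y], s[~y], alternative="two-sided").statistic
            assert roc(s, y).auc == pytest.approx(u / (n_pos * n_neg), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1.0, 2.0], [True, True])


class TestPatientSplit:
    def _measurements(self, spec):
        """spec: list of (patient, feature value per measurement, label)."""
        feats, pids, labels = [], [], []
        for pid, values, lab in spec:
            for v in values:
                feats.append([v, v])
                pids.append(pid)
                labels.append(lab)
        return np.array(feats, float), np.array(pids), np.array(labels)

    def test_separable_measurements_all_correct(self):
        x, pid, y = self._measurements([
            ("A", [3, 3, 3], True), ("B", [-3, -3], False),
            ("C", [3.2, 2.8], True), ("D", [-2.9, -3.1], False),
        ])
        verdicts = patient_split_classifier(x, pid, y, ["A", "B", "C", "D"], seed=0)
        assert [v.patient_id for v in verdicts] == ["C", "D"]
        assert all(v.verdict == "correct" for v in verdicts)

    def test_mixed_predictions_are_undecided_and_inverted_wrong(self):
        x, pid, y = self._measurements([
            ("A", [3, 3, 3], True), ("B", [-3, -3], False),
            ("C", [3.0, -3.0], True),      # one measurement on each side
            ("D", [-3.0, -3.0], True),     # consistently on the wrong side
        ])
        verdicts = {v.patient_id: v.verdict
                    for v in patient_split_classifier(x, pid, y, ["A", "B", "C", "D"], seed=0)}
        assert verdicts == {"C": "undecided", "D": "wrong"}

    def test_single_class_training_split_rejected(self):
        x, pid, y = self._measurements([
            ("A", [1, 1], True), ("B", [2, 2], True),
            ("C", [1, 2], True), ("D", [0, 0], False),
        ])
        with pytest.raises(ValueError):
            patient_split_classifier(x, pid, y, ["A", "B", "C", "D"], seed=0)
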