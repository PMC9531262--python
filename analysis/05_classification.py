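#!/usr/bin/env python
"""Classification of positive patient-days (ICDSC or SOFA >= 3).

Uses the two GA components (SOFA, ICDSC targets) as classifier inputs:
(a) fivefold patient-grouped cross-validated SVM with accuracy,
sensitivity, specificity and the ROC curve; (b) the first-10/last-10
per-patient classifier with correct/wrong/undecided verdicts on
measurement-level components.  Writes results/classification.json,
results/roc.csv and an ROC figure.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from acg import Individual, build_feature_table, load_cohort, standardize
from acg.classify import crossval_svm, label_positive, patient_split_classifier, roc
from acg.ga import pc1_scores

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=3)
args = parser.parse_args()

cohort = load_cohort(args.results / "cohort")
table = standardize(build_feature_table(cohort))
best = {t: Individual(tuple(json.loads(
            (args.results / f"ga_{t}.json").read_text())["selected_features"]))
        for t in ("sofa", "icdsc")}
comps = np.column_stack([pc1_scores(best[t], table) for t in ("sofa", "icdsc")])

labels = np.array([label_positive(r) for r in cohort.records])
groups = np.array([r.patient_id for r in cohort.records])
cv = crossval_svm(comps, labels, k=5, seed=args.seed, groups=groups,
                  row_keys=cohort.patient_days())
print(f"fivefold CV: accuracy {cv.mean_accuracy:.2f}%, "
      f"sensitivity {cv.mean_sensitivity:.2f}%, specificity {cv.mean_specificity:.2f}%")

have = ~np.isnan(cv.scores)
curve = roc(cv.scores[have], cv.labels[have])
print(f"ROC AUC {curve.auc:.3f}")
pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
    args.results / "roc.csv", index=False)

fig, ax = plt.subplots(figsize=(4.5, 4.5))
ax.plot(curve.fpr, curve.tpr)
ax.plot([0, 1], [0, 1], ls="--", c="grey")
ax.set_xlabel("false-positive rate")
ax.set_ylabel("true-positive rate")
ax.set_title(f"ROC (AUC = {curve.auc:.3f})")
(args.results / "figures").mkdir(exist_ok=True, parents=True)
fig.savefig(args.results / "figures" / "roc.png", dpi=150)

mtable = standardize(build_feature_table(cohort, per_measurement=True))
mcomps = np.column_stack([pc1_scores(best[t], mtable) for t in ("sofa", "icdsc")])
lab_of = {(r.patient_id, r.day): label_positive(r) for r in cohort.records}
mpid = np.array([p for p, _, _ in mtable.row_index])
mlabels = np.array([lab_of[(p, d)] for p, d, _ in mtable.row_index])
order = list(dict.fromkeys(r.patient_id for r in cohort.records))
verdicts = patient_split_classifier(mcomps, mpid, mlabels, order, seed=args.seed)
counts = {k: sum(v.verdict == k for v in verdicts)
          for k in ("correct", "wrong", "undecided")}
print(f"first-10/last-10 verdicts: {counts}")

(args.results / "classification.json").write_text(json.dumps({
    "cv": cv.to_dict(), "auc": curve.auc,
    "verdicts": [v.__dict__ for v in verdicts], "verdict_counts": counts,
}, indent=2, sort_keys=True))
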