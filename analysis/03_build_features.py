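#!/usr/bin/env python
"""Build the >1,000-column patient-day feature table for GA selection.

Writes results/features.csv (feature matrix) and results/targets.csv
(aligned clinical columns).
"""

import argparse
from pathlib import Path

from acg import build_feature_table, load_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = load_cohort(args.results / "cohort")
table = build_feature_table(cohort)

df = table.to_frame()
df.index.names = ["patient_id", "day"]
df.to_csv(args.results / "features.csv", float_format="%.17g")
targets = table.targets.copy()
targets.insert(0, "day", [d for _, d in table.row_index])
targets.insert(0, "patient_id", [p for p, _ in table.row_index])
for col in table.meta.columns:
    targets[col] = table.meta[col].to_numpy()
targets.to_csv(args.results / "targets.csv", index=False, float_format="%.17g")

print(f"feature table: {table.n_rows} patient-days × {table.n_features} features")
print(f"written to {args.results / 'features.csv'}")
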