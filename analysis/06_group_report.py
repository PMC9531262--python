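#!/usr/bin/env python
"""Statistical report: arm comparison at inclusion and correlation table.

Prints median (quartile) rows with rank-test p-values per clinical
parameter, the chi-squared CAM-ICU comparison, and the absolute Pearson
correlations of each parameter with the dimensionality summary and with
its GA component.  Writes results/report.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from acg import Individual, build_feature_table, load_cohort, standardize
from acg.dimensionality import patient_day_dimensionality
from acg.ga import pc1_scores
from acg.statsreport import CONTINUOUS_PARAMS, correlation_table, group_compare

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = load_cohort(args.results / "cohort")
table = standardize(build_feature_table(cohort))
dims = patient_day_dimensionality(cohort)
by_key = {(d.patient_id, d.day): d for d in dims}
dims_aligned = [by_key[k] for k in table.row_index]

ga = {}
for param in CONTINUOUS_PARAMS:
    path = args.results / f"ga_{param}.json"
    if path.exists():
        ind = Individual(tuple(json.loads(path.read_text())["selected_features"]))
        ga[param] = pc1_scores(ind, table)

print("=== arm comparison, day 1 (median [q25/q75], rank test) ===")
comparison = group_compare(cohort, day=1) + group_compare(
    cohort, parameters=("cam_icu",), day=1)
for row in comparison:
    flag = "*" if row.significant else " "
    print(f"{row.parameter:10s} CG {row.cg_median:7.2f} "
          f"[{row.cg_q25:6.2f}/{row.cg_q75:6.2f}]  "
          f"SG {row.sg_median:7.2f} [{row.sg_q25:6.2f}/{row.sg_q75:6.2f}]  "
          f"p={row.p_value:.4f}{flag} ({row.test})")

print("=== absolute Pearson correlations (dimensionality vs GA) ===")
corr = correlation_table(dims_aligned, ga, table.targets)
for row in corr:
    print(f"{row.parameter:10s} dimensionality {row.r_dimensionality:.2f}   "
          f"GA {row.r_ga:.2f}")

(args.results / "report.json").write_text(json.dumps({
    "group_comparison": [r.to_dict() for r in comparison],
    "correlations": [r.to_dict() for r in corr],
}, indent=2, sort_keys=True, default=lambda o: None))
print(f"written to {args.results / 'report.json'}")
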