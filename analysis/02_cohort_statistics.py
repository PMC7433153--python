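#!/usr/bin/env python
"""Cohort-level statistics on a synthetic table drawn from the published
group summaries.

Generates one cohort (22 MVI-negative / 14 MVI-positive) from the reported
NIC means +/- SDs, runs the full statistical battery (group comparison,
ROC with DeLong CIs and Youden cutoffs, univariate screen at p < 0.10,
multivariate logistic regression with the NIC collinearity guard), and
additionally estimates the expected outer-layer-1 AUC by averaging over
200 replicate cohorts.

Writes results/cohort_report.json and results/cohort_auc_replicates.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dectpeel import CohortSpec, PipelineConfig, generate_cohort, roc_auc, run_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--replicates", type=int, default=200)
args = parser.parse_args()

outdir = Path(__file__).resolve().parents[1] / "results"
outdir.mkdir(exist_ok=True)

table = generate_cohort(CohortSpec(seed=args.seed))
report = run_cohort(table, PipelineConfig(seed=args.seed))
(outdir / "cohort_report.json").write_text(
    json.dumps(report.to_dict(), indent=2, default=float) + "\n")

print("Single synthetic cohort (n = 22/14):")
print(report.group_comparison[["feature", "mean_neg", "mean_pos", "p_value"]]
      .to_string(index=False))
print("\nROC (AUC with 95% DeLong CI, Youden cutoff):")
print(report.roc[["feature", "auc", "ci_low", "ci_high", "cutoff",
                  "sensitivity", "specificity"]].round(3).to_string(index=False))
print(f"\nScreened in at p < 0.10: {report.screened_in}")
if report.multivariate is not None:
    print(f"Multivariate ORs: "
          f"{ {k: round(v, 2) for k, v in report.multivariate.odds_ratios.items()} }"
          f" (collinear NICs dropped: {report.multivariate.dropped_collinear})")

rng = np.random.default_rng(args.seed)
aucs = []
for _ in range(args.replicates):
    t = generate_cohort(
        CohortSpec(features={"nic_outer1_2mm": (0.07, 0.03, 0.10, 0.03)}), rng=rng)
    aucs.append(roc_auc(t["nic_outer1_2mm"], t["mvi"]).auc)
mean_auc, sd_auc = float(np.mean(aucs)), float(np.std(aucs, ddof=1))
(outdir / "cohort_auc_replicates.json").write_text(json.dumps(
    {"replicates": args.replicates, "mean_auc": mean_auc, "sd_auc": sd_auc},
    indent=2) + "\n")
print(f"\nOuter-layer-1 NIC over {args.replicates} replicate cohorts: "
      f"mean AUC {mean_auc:.3f} (replicate SD {sd_auc:.3f}); the binormal "
      f"closed form for these group parameters is 0.760.")
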