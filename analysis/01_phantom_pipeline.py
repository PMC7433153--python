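#!/usr/bin/env python
"""End-to-end phantom study: does the pipeline recover the rim signal?

Builds a matched cohort of digital dual-energy phantoms — MVI-positive
cases carry a peritumoral enhancing rim (+0.5 mg/mL iodine in the first
2 mm outside the tumor margin), negatives do not — runs every case through
the full chain (decomposition, semiautomatic segmentation from a diameter
line, layer peeling at 2 and 4 mm, quantification), and reports how well
outer-layer-1 NIC separates the groups.

Writes results/phantom_features.csv and results/phantom_pipeline.json.
"""

import argparse
import json
from pathlib import Path

from dectpeel import PipelineConfig, roc_auc, simulate_mvi_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--n-per-group", type=int, default=8)
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

cfg = PipelineConfig(seed=args.seed)
table = simulate_mvi_cohort(args.n_per_group, args.n_per_group, cfg)

outdir = Path(__file__).resolve().parents[1] / "results"
outdir.mkdir(exist_ok=True)
table.to_csv(outdir / "phantom_features.csv", index=False)

summary = {}
for feat in ("nic_outer1_2mm", "nic_outer2_2mm", "nic_tumor_2mm", "nic_outer1_4mm"):
    r = roc_auc(table[feat], table["mvi"])
    summary[feat] = {
        "auc": round(r.auc, 3),
        "mean_neg": round(float(table.loc[table.mvi == 0, feat].mean()), 4),
        "mean_pos": round(float(table.loc[table.mvi == 1, feat].mean()), 4),
    }
(outdir / "phantom_pipeline.json").write_text(json.dumps(summary, indent=2) + "\n")

print(f"{2 * args.n_per_group} phantoms through the full pipeline")
for feat, s in summary.items():
    print(f"  {feat}: AUC {s['auc']:.3f}  "
          f"(group means {s['mean_neg']:.3f} vs {s['mean_pos']:.3f})")
print("The rim lives in outer layer 1, so its NIC should separate the groups "
      "cleanly (AUC near 1) while the intratumoral NIC should not.")
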