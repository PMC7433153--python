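#!/usr/bin/env python
"""Arithmetic that is fully determined by the published 2x2 counts.

The qualitative reader calls are public as counts: peritumoral enhancement
in 8/22 MVI-negative vs 9/14 MVI-positive patients; non-smooth margins in
10/22 vs 10/14. Everything derivable from those counts is recomputed here:
chi-square p-values, the AUC of each binary feature, and the Woolf odds
ratios.

Writes results/printed_counts.json.
"""

import json
from pathlib import Path

import numpy as np

from dectpeel import TwoByTwo, chi_square_2x2, odds_ratio, roc_auc

# (flagged MVI+, total MVI+, flagged MVI-, total MVI-)
FEATURES = {
    "peritumoral_enhancement": (9, 14, 8, 22),
    "nonsmooth_margin": (10, 14, 10, 22),
}

out = {}
for name, (pos_f, n_pos, neg_f, n_neg) in FEATURES.items():
    t = TwoByTwo(a=pos_f, b=n_pos - pos_f, c=neg_f, d=n_neg - neg_f)
    stat, p = chi_square_2x2(t)
    o, lo, hi = odds_ratio(t)
    scores = np.r_[np.repeat([1, 0], [pos_f, n_pos - pos_f]),
                   np.repeat([1, 0], [neg_f, n_neg - neg_f])]
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    r = roc_auc(scores, labels)
    out[name] = {
        "prevalence_pos": round(pos_f / n_pos, 3),
        "prevalence_neg": round(neg_f / n_neg, 3),
        "chi2": round(stat, 3), "chi2_p": round(p, 3),
        "odds_ratio": round(o, 2), "or_ci": [round(lo, 2), round(hi, 2)],
        "auc": round(r.auc, 3),
        "auc_ci": [round(r.ci_low, 3), round(r.ci_high, 3)],
    }

outdir = Path(__file__).resolve().parents[1] / "results"
outdir.mkdir(exist_ok=True)
(outdir / "printed_counts.json").write_text(json.dumps(out, indent=2) + "\n")

for name, s in out.items():
    print(f"{name}: present in {s['prevalence_pos']:.1%} of MVI+ vs "
          f"{s['prevalence_neg']:.1%} of MVI-; chi2 p = {s['chi2_p']:.2f}; "
          f"OR = {s['odds_ratio']:.2f} {tuple(s['or_ci'])}; "
          f"AUC = {s['auc']:.2f}")
print("Neither qualitative feature reaches p < 0.05 on these counts; their "
      "AUCs (0.64, 0.63) sit below the quantitative outer-layer-1 NIC.")
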