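# dectpeel

Volumetric dual-energy CT (DECT) iodine quantification of peritumoral and
intratumoral layers, for predicting microvascular invasion (MVI) of
hepatocellular carcinoma (HCC).

## The problem

MVI — tumor cells inside small vessels, visible only under the microscope —
drives early recurrence of HCC after resection, but can only be confirmed
on the surgical specimen. Arterial-phase peritumoral enhancement hints at
MVI preoperatively, yet qualitative reader calls are subjective. DECT
offers a quantitative alternative: the 80 kV / Sn150 kV channel pair lets
each voxel be decomposed into a virtual-non-contrast (VNC) component and an
iodine concentration `c` (mg/mL),

    HU_low  = vnc + s_low  · c
    HU_high = vnc + s_high · c ,

so peritumoral enhancement becomes a measurable iodine concentration. This
package implements the full analysis chain for that idea:

1. **Decomposition** — mixed-energy image (`0.6·low + 0.4·high`), VNC image
   and iodine map from the two-material model above.
2. **Segmentation** — semiautomatic volumetric tumor segmentation grown
   from a user-drawn maximal-diameter line; liver segmentation; volume and
   3-D Feret diameter.
3. **Layer peeling** — Euclidean-distance bands of thickness *t* (2 mm
   default, 4 mm variant) outside (outer layers 1, 2) and inside (inner
   layers 1, 2) the tumor margin, plus five VOIs (tumor ± layers), with
   outer layers clipped to the liver minus vessel exclusions.
4. **Quantification** — per region: mean HU, total and vital (enhancing)
   iodine concentration, and the normalized iodine concentration
   `NIC = vital IC / aortic IC`, which removes inter-patient contrast
   variation.
5. **Cohort statistics** — Mann-Whitney and chi-square group tests, ROC
   with DeLong 95% CIs and paired AUC comparison, Youden-optimal cutoffs,
   Woolf odds ratios, univariate screen (p < 0.10) feeding a multivariate
   logistic regression with a collinearity guard among NIC features, and
   reliability metrics (ICC, Cohen κ).

Because no clinical cohort ships with the package, a **synthetic-data
module** provides (a) voxel-level DECT phantoms — liver, hyper-enhancing
tumor, aorta, and an optional peritumoral enhancing rim for MVI-positive
cases — generated by the exact forward model of the decomposition, with
ground-truth masks and iodine; and (b) cohort feature tables drawn from
the published per-group NIC summaries (zero-truncated normals), so every
stage is testable end to end.

## Worked example

An MVI-positive phantom (enhancing rim: +0.5 mg/mL iodine within 2 mm of
the tumor margin) through the whole pipeline:

```python
from dectpeel import (CalibrationMatrix, PhantomSpec, PipelineConfig,
                      diameter_line_for_phantom, generate_phantom, run_case)

spec = PhantomSpec(rim=True, noise_sd=5.0, seed=42)   # MVI-positive phantom
phantom = generate_phantom(spec, CalibrationMatrix())
case = run_case(
    phantom.study, phantom.masks["aorta"], PipelineConfig(),
    line=diameter_line_for_phantom(spec),   # the reader's diameter gesture
    liver_mask=phantom.masks["liver"],
)
```

prints, via the fields of `case.row`:

```
tumor volume      4.16 mL
max diameter      20.0 mm
aortic iodine     10.00 mg/mL
NIC outer layer 1 0.150
NIC outer layer 2 0.101
NIC tumor         0.250
```

The rim lives entirely in outer layer 1, so its NIC (0.150) stands above
the parenchymal level seen in outer layer 2 (0.101 — the liver's baseline
1 mg/mL against a 10 mg/mL aorta); a matched rim-free phantom yields
≈ 0.10 in both. Classifying `nic_outer1_2mm` against the published
decision threshold of 0.082 calls this case MVI-positive.

The numbered drivers under `analysis/` run the larger studies and write
their tables to `results/`:

- `01_phantom_pipeline.py` — matched phantom cohort through the full
  pipeline; outer-layer-1 NIC separates rim-positive from rim-negative
  cases with AUC 1.000 while intratumoral NIC does not (AUC ≈ 0.5).
- `02_cohort_statistics.py` — full statistical battery on a synthetic
  cohort (22 MVI-negative / 14 MVI-positive) drawn from the published NIC
  group summaries, plus a 200-replicate estimate of the expected
  outer-layer-1 AUC.
- `03_printed_counts.py` — everything determined by the published 2×2
  reader counts: chi-square p-values (0.10, 0.13), odds ratios
  (3.15 [0.78–12.73], 3.00 [0.72–12.55]) and binary-feature AUCs
  (0.64, 0.63).

A `dectpeel` console script exposes the stages individually
(`phantom`, `decompose`, `segment`, `peel`, `quantify`, `case`, `cohort`)
over NIfTI volumes, CSV tables and JSON configs; see `dectpeel --help`.

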