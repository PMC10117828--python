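# spatimm

Spatial immune profiling of serial-section immunohistochemistry (IHC)
cohorts.

Pathology labs routinely stain serial sections of a tumor block for one
marker each (e.g. CD3, CD4, CD8, CD19, CD163 for immune cells and
cytokeratin AE1/AE3 for tumor cells).  Because each marker sits on its own
physical slide, studying how immune-cell types distribute *relative to each
other* and to the tumor requires (1) registering the slides into a common
frame and (2) quantifying spatial statistics on the aligned cell
coordinates.  `spatimm` implements that full analysis as a tested,
reusable Python pipeline for cohorts of patients with survival follow-up,
aimed at computational-pathology and tumor-immunology researchers working
from cell-detection exports (e.g. QuPath) rather than raw pixels.

## What it computes

Per patient, from registered positive-cell coordinates, a 47-parameter
vector:

- **Region densities** (15): positive cells/mm² per marker in the tumor
  core *TC*, the invasive margin *IM* (the band within 100 µm of the
  invasive front), and their union *TC+IM*.
- **Hotspots** (15): the slide is dissected into 1000 × 1000-pixel tiles
  (200 µm at 0.2 µm/pixel); a tile is *effective* when at least half its
  area lies in the TC; the three highest per-tile densities per marker are
  Hotspot1–3.
- **Colocalization** (16): for markers *l* and *c* with tile proportions
  `p_i^l`, `p_i^c` over the same R tiles, the Morisita–Horn index

      MH = 2 Σ_i p_i^l p_i^c / (Σ_i (p_i^l)² + Σ_i (p_i^c)²)  ∈ [0, 1],

  for all immune-marker pairs, each marker vs CK, and pooled immune cells
  vs CK.
- **Immunoscore** (1): CD3 and CD8 densities in TC and IM are converted to
  within-cohort percentiles; the score is the mean of the four percentiles,
  dichotomized low (≤ 25) vs high (> 25).

At cohort level: Student-t comparisons between recurrence (ER/LR) and
distant-metastasis (DM/non-DM) groups, ROC-derived optimal cutoffs
(Youden's J), Kaplan–Meier curves with log-rank tests for each
dichotomized parameter against disease-free and overall survival,
multivariate Cox models with clinical covariates, and a repeat of the
analyses on the advanced-stage (IIB+) subset.

Registration follows the downsample-then-transfer scheme: each slide's
cell detections are rasterized to a ~500-pixel working image, aligned to
the middle slide of the stack by a rigid normalized-cross-correlation
search plus a regularized local-correlation displacement field, and the
field is interpolated back at full resolution to transfer every cell
coordinate into the reference frame.

A synthetic-cohort generator (`spatimm.synthetic`) produces cohorts with
the same file layout and known ground truth — clustered marker point
patterns with two-fold margin enrichment for lymphocytes, planted
per-slide misalignments, and survival times linked to immune densities by
a proportional-hazards model — so every stage is testable end to end
without patient data.

## Worked example

```python
from spatimm.config import PipelineConfig
from spatimm.pipeline import run_pipeline
from spatimm.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_patients=12, seed=7))
result = run_pipeline(cohort, PipelineConfig(), outdir="demo_out")
cols = ["TC-CD3", "IM-CD3", "Hotspot1-CD3", "CD8-CD163", "CK-Immune", "Immunoscore"]
print(result.parameters[cols].head(4).round(2).to_string())
```

```
              TC-CD3   IM-CD3  Hotspot1-CD3  CD8-CD163  CK-Immune  Immunoscore
patient_id
patient_000  1033.39  1399.08        2050.0       0.92       0.96        25.00
patient_001  1022.40  1581.73        1600.0       0.91       0.95        58.33
patient_002  1043.01  1713.66        3425.0       0.91       0.96        58.33
patient_003  1121.81  1655.20        2325.0       0.86       0.96        62.50
```

CD3 density is higher in the invasive margin than in the tumor core
(the generator plants a two-fold enrichment), hotspot densities exceed the
regional means as they should, the MH indices near 0.9 reflect the shared
clustered architecture of the synthetic slides, and patient_000's
Immunoscore of exactly 25 falls in the "low" category (the 0–25 band is
inclusive).  The univariate survival table then reports, per parameter and
endpoint, the ROC cutoff and log-rank p:

```
print(result.tables["univariate_all"].loc[["TC-CD3", "CD8-CD163"]].round(4).to_string())

             DFS_cutoff   DFS_p  OS_cutoff    OS_p
TC-CD3        1106.4874  0.0190   956.4534  0.0511
CD8-CD163        0.8719  0.1578     0.8942  0.1941
```

The same workflow is available from the shell:

```bash
spatimm simulate --n-patients 68 --seed 1 --outdir cohort/
spatimm run cohort/ --outdir results/
spatimm report results/
```

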