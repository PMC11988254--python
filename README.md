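# autoprofiler

Image-based **temporal profiling of autophagy phenotypes** from two-channel
time-lapse fluorescence microscopy of a tandem pHluorin-mKate2-LC3 reporter.

Autophagy is usually quantified by vesicle counts or mean reporter
intensity, which miss most of the morphological response to a perturbation.
`autoprofiler` instead tracks single cells through time and measures a
catalogue of 949 morphological features per cell per timepoint — structure,
intensity and texture of the whole cell, of autophagosomes (AP; puncta
visible in both channels) and of autolysosomes (AL; puncta whose pH-sensitive
channel is quenched, visible in the red channel only) — and turns those
temporal profiles into treatment classification, explainable feature
importance and quantitative prediction of autophagic cargo degradation.

It is aimed at quantitative cell biologists running high-content autophagy
screens with LC3 tandem reporters who want more than `AP_number` per cell.

## What it computes

1. **Imaging** — rolling-ball background subtraction (0.98 um ball), puncta
   detection at the ~0.8 um spot scale with channel-specific contrast
   thresholds (5 GFP / 6 TRITC), AP/AL classification by channel overlap
   logic, watershed cell segmentation (or externally supplied masks) and
   greedy IoU tracking with a division-discard rule.
2. **Features** — the 949-name catalogue: 72 base features per object
   (10 structural, 9 intensity, 28 Haralick texture, 25 Zernike moments),
   aggregated per cell over vesicles with six descriptive statistics, plus
   vesicle counts and 11 whole-cell-only features.
3. **Profiles** — robust plate-wise standardization against DMSO cells,

       z = (x − median(X_DMSO)) / (1.2532 · MAD(X_DMSO)),

   and feature selection by |median z| ≥ 0.5 with Benjamini–Hochberg-adjusted
   Mann–Whitney p < 0.05 against DMSO.
4. **Classification & explanation** — 1000-tree entropy random forest on
   cells × (feature, timepoint) matrices after |r| ≥ 0.75 correlation
   pruning, stratified 5-fold micro-F1, and exact tree-path Shapley
   attributions with grouped (entity × type) importance and a top-15 table.
5. **Similarity & prediction** — median treatment profiles, average-linkage
   clustering, Pearson profile similarity to a reference inducer
   (100 nM rapamycin by default), and an OLS **standard curve** mapping
   similarity to normalized cargo degradation, with 95% confidence and
   prediction intervals, used to predict the degradative output of new
   treatments from imaging alone.

Because the raw microscopy behind this kind of study is rarely public, the
package ships a first-class synthetic-data generator (`autoprofiler.synthgen`)
producing two-channel scenes with ground-truth masks, puncta and lineage, and
feature tables with programmed effect sizes, so every stage is testable.

## Worked example

```python
import numpy as np
from autoprofiler import ScenePreset, generate_scene, DetectionParams
from autoprofiler.workflow import extract_scene_features
from autoprofiler.profiles import modified_z, drop_nan_features, select_significant

dmso = ScenePreset(treatment_label="DMSO", n_cells=4, seed=0)
rapa = ScenePreset(treatment_label="rapamycin_100nM", n_cells=4, seed=1,
                   ap_rate=8.0, intensity_trend=(0.85, 1.0))

tables = []
for preset in (dmso, rapa):
    frames, truth = generate_scene(preset, n_timepoints=2)
    tables.append(extract_scene_features(frames, DetectionParams(),
                                         labels=truth.labels, nan_mode="zero"))
import pandas as pd
table = pd.concat(tables, ignore_index=True)
std = modified_z(drop_nan_features(table))
rec = select_significant(std, "rapamycin_100nM", timepoint=0.5)
print(table.groupby("treatment")["AP_number"].mean().round(2))
print(f"{int(rec.significant.sum())} significant features at 0.5 h")
```

prints

```
treatment
DMSO               2.88
rapamycin_100nM    7.38
Name: AP_number, dtype: float64
0 significant features at 0.5 h
```

The rapamycin-like preset (Poisson mean 8 AP/cell) more than doubles the
mean detected autophagosome count per cell relative to DMSO (2.9 → 7.4), while
with only 4 cells per arm the rank-test/FDR selection rule correctly refuses
to call any single feature significant — the specificity half of the
selection design. At realistic arm sizes (hundreds of cells) planted effects
of ≥ 0.5 robust SD are recovered; see `tests/test_acceptance.py`.

A YAML-driven end-to-end run (simulate → detect → track → extract →
standardize → select → classify → explain → similarity) is available as

```bash
autoprofiler run-all config.yaml
```

with per-stage subcommands (`simulate`, `normalize`, `select`, `classify`,
`explain`, `cluster`, `similarity`, `predict`) for existing CSV tables.

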