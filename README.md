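# myoradiomics

Robustness analysis of 2D radiomic features from quantitative cardiac
T1/T2 maps under image preprocessing: resampling voxel size, gray-level
bin width, and spatial filtering.

## The problem

Radiomic features — shape, intensity and texture descriptors extracted
from a region of interest — are increasingly computed from myocardial
T1 and T2 parametric maps, whose pixel values are tissue relaxation
times in milliseconds. Before feature extraction, maps are typically
resampled to a common in-plane spacing, discretized into integer gray
levels, and optionally filtered. Each of these choices can move the
feature values, so anyone pooling multi-centre mapping data needs to
know *which* features are stable and by how much.

This package makes that assessment reproducible end to end without
patient data: a seeded synthetic-cohort generator emulates single-slice
myocardial maps (annular ROI, per-subject acquisition spacing,
spatially correlated texture), a complete 2D radiomic engine extracts
the 98-feature inventory, and a statistics layer quantifies the effect
of each preprocessing element.

## What is computed

**Features** (98 per unfiltered coordinate; 89 — all but shape — per
filtered map): 9 2D shape, 16 first-order (14 intensity statistics
computed *before* discretization, plus histogram Entropy and
Uniformity), and 73 texture features from GLCM (22), GLRLM (16),
GLSZM (16), GLDM (14, dependence threshold α = 0) and NGTDM (5),
with a Chebyshev distance-1 neighbourhood. Directional GLCM/GLRLM
features are computed at 0°, 45°, 90°, 135° and averaged over angles.
Gray levels use fixed bin widths *W* with bin edges at integer
multiples of *W*:

```
level(x) = floor(x / W) − floor(min_ROI / W) + 1,   N_g = max level.
```

**Effects.** Three experimental designs, mirrored on both modalities:

* **A** — vary resampling voxel size (1.8 … 2.4 mm, cubic B-spline, 7
  values) at each fixed bin width;
* **B** — vary bin width (T1: 3.60 … 6.40 ms; T2: 0.49 … 0.57 ms; 9
  values) at each fixed voxel size;
* **C** — vary the spatial filter (4 stationary Daubechies-3 wavelet
  sub-bands, gradient magnitude, square, square-root) at fixed
  2.1 mm / 6 ms (T1) or 0.56 ms (T2).

**Statistics.** Per feature and fixed condition, variability across the
varied element is quantified by the two-way mixed-effects, single
rater, absolute-agreement intraclass correlation

```
ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)),
```

banded as high (≤ 0.5), considerable (≤ 0.75), moderate (≤ 0.9) or low
(≤ 1) relative variability; by per-subject coefficients of variation
CV = 100·SD/|mean| with median summaries; and by the repeated-measures
correlation r_rm (ANCOVA with a common slope, df = N(k−1) − 1,
Bonferroni-corrected) between feature estimates and the varied
parameter.

## Worked example

```python
from myoradiomics.cohort import CohortSpec, generate_cohort
from myoradiomics.pipeline import EffectDesign, run_effect, analyze_effect, BIN_WIDTHS_MS

cohort = generate_cohort(CohortSpec.t1_default(n_subjects=8, seed=0))
design = EffectDesign("B", (2.1,), BIN_WIDTHS_MS["T1"])   # vary bin width
table = run_effect(cohort, design)                        # 8 × 9 × 98 records
results = analyze_effect(table, design)
print(results.summary())
```

prints

```
Preprocessing robustness results — effect B
========================================================
features analysed:      98
ICC matrices:           98
subject rows dropped:   0

ICC band counts (matrices):
  considerable 55
  low          28
  moderate     11
  high         4

median CV%: min=0.00  median=4.70  max=79.97
rmcorr: 72/98 tests significant (Bonferroni, alpha=0.05)
```

Reading `results.icc_table` for individual features:

```
     shape Sphericity   ICC = 1.000  band = low
firstorder Mean         ICC = 1.000  band = low
firstorder Entropy      ICC = 0.610  band = considerable
```

Shape and intensity-statistical features sit at ICC = 1.000 with
CV = 0% because they are computed before discretization — varying the
bin width cannot move them. Histogram and texture features do respond
to the bin width (Entropy above), and most correlate significantly
with it under the repeated-measures test.

The same analysis is available from the shell:

```sh
myoradiomics run-all --n-subjects 8 --seed 0 --modality T1 --out results/
```

which writes the feature grids, ICC/CV/rmcorr tables and a JSON run
manifest.

## Layout

| Module | Contents |
| --- | --- |
| `myoradiomics.cohort` | synthetic cohort generator (`CohortSpec`, `generate_cohort`) |
| `myoradiomics.io` | NIfTI read/write, cohort manifests |
| `myoradiomics.preprocess` | B-spline resampling, fixed-bin-width discretization, filter bank |
| `myoradiomics.features` | registry, texture matrices, feature formulas, extraction engine |
| `myoradiomics.stats` | ICC, CV, rmcorr, Bonferroni |
| `myoradiomics.model` | `PreprocessingRobustness` / `RobustnessResults` |
| `myoradiomics.pipeline` | effect designs, grid orchestration, manifests |
| `myoradiomics.cli` | `simulate`, `extract`, `analyze`, `run-all` |

See `docs/methods.md` for the modelling assumptions, parameter
defaults and numerical conventions.
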