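# Methods

This note documents the models, conventions and design choices behind
the package; the README shows how to run it.

## Synthetic cohort model

Each subject is a single-slice 2D map of relaxation times (ms) with a
binary annular ROI standing in for a mid-ventricular short-axis
myocardium segmentation. The generative model, per subject *s*:

* **Grid and spacing.** A fixed matrix (default 126 × 192) with an
  isotropic in-plane spacing drawn uniformly from a cohort interval
  (default 1.77–2.34 mm). Heterogeneous native spacing is what makes
  the resampling experiment non-trivial.
* **ROI.** An annulus in physical coordinates (defaults: inner radius
  25 mm, outer 32 mm, centred on the grid), about 230–360 pixels
  depending on spacing. Pixel count scales as π(r_o² − r_i²)/spacing².
* **Intensities.** `value(s, x) = μ_s + a_s · F_s(x)` inside the ROI,
  where
  * `μ_s ~ Normal(value_mean_ms, between_subject_sd_ms²)` (defaults
    1030 ± 60 ms for T1, 50 ± 3 ms for T2). The additive subject mean
    provides the between-subject variance that ICC resolves. Absolute
    myocardial means are configuration, not claims.
  * `F_s` is white Gaussian noise convolved with a Gaussian kernel of
    physical width `correlation_length_mm` (default 4 mm) and divided
    by the kernel's L2 norm, giving unit pointwise (ensemble) variance
    at any smoothing width. In the infinite-correlation limit the
    field is spatially constant, so the within-ROI range tends to 0
    rather than being re-inflated by an empirical normalisation.
  * `a_s = A · exp(ε_s)`, `ε_s ~ Normal(0, σ_ln²)` with σ_ln chosen so
    the multiplier's coefficient of variation equals
    `between_subject_range_cv` (default 0.30, median multiplier 1).
    Cohorts differ in myocardial heterogeneity, not only mean value;
    without this term, shift-invariant features (histogram Entropy,
    most texture features) would carry no between-subject variance and
    every ICC involving them would collapse towards 0.
  * The base amplitude is `A = target_median_range_ms / 4.54`. The
    constant 4.54 is the expected median within-ROI range of the
    unit-variance field for the default ring and correlation length,
    fitted once empirically; with it, the median across-subject
    within-ROI range tracks the target (265 ms T1 / 26 ms T2) with
    < 5% bias over seeds.
* **Background** outside the ROI is a distinct constant (30% of the
  cohort mean) plus noise. It is never used by features but exercises
  mask handling.

What the generator does **not** emulate: MR acquisition physics
(MOLLI/T2-prep fitting error, banding), motion, partial-volume at the
blood pool interface, segmentation variability, non-stationary
pathology-related texture (e.g. focal fibrosis), and 3D geometry.
Consequently, passing tests demonstrate correctness and the
*structural* behaviour of the statistics (what cannot move, what must
move, directionality), not clinical-magnitude ICC/CV values for real
patients.

## Preprocessing

* **Resampling**: cubic B-spline (SimpleITK) to an isotropic target
  spacing, origins of source and target grids aligned; the mask is
  resampled nearest-neighbour and re-binarised at 0.5. The target grid
  has `floor((n−1)·s/t) + 1` points per axis so every target point
  stays inside the source sample lattice (no extrapolation). The
  implementation agrees with an independent tensor-product B-spline
  evaluation (`scipy.ndimage.map_coordinates`, mirror boundary) to
  1e-12. Resampling that empties the ROI raises a degenerate-ROI
  error.
* **Discretization**: fixed bin width *W*, bin edges anchored at
  integer multiples of *W* (default, matching common extraction
  software for quantitative maps): `level = floor(x/W) −
  floor(min/W) + 1`. ROI-minimum anchoring is available as an option.
  The level count for a range *R* is `floor(R/W) + 1` or `+ 2`
  depending on where the minimum falls relative to the bin grid;
  `count_levels` reports either phase extreme. The stated T1 bin
  widths on the 265 ms reference range give 42–75 levels, inside the
  30–130 design window.
* **Filters**: `original`, four single-level stationary (undecimated)
  Daubechies-3 wavelet sub-bands `wavelet-LL/LH/HL/HH` (first letter =
  horizontal/column axis, second = vertical/row axis; odd grids are
  wrap-padded to even and cropped back), spacing-aware gradient
  magnitude, `square`, and `square-root`. By default square and
  square-root rescale onto the original intensity range
  (`x²/max|x|`, `sign(x)·√(|x|·max|x|)`): a squared T1 map otherwise
  spans ~5·10⁵ ms, i.e. ~10⁵ gray levels at the fixed 6 ms bin width,
  which is neither computable as a dense co-occurrence matrix nor
  consistent with the 30–130 level design window that the filter
  experiment is meant to respect. `FilterSpec(name,
  intensity_rescale=False)` gives the literal per-pixel algebra.
  Filtered maps are discretized with the effect-C fixed bin widths
  applied to the (rescaled) filtered intensities directly.

## Feature engine

Levels run 1..N_g; empty levels are kept as zero rows/columns so that
fixed-bin-width semantics stay meaningful (weighted sums over empty
rows vanish). Matrices are restricted to the ROI: co-occurrence pairs,
runs, zones, dependences and neighbourhood means never cross the mask
boundary. GLCMs are symmetric and normalised per direction; GLCM and
GLRLM feature values are averaged over the four angles (feature-level
averaging, not matrix-level). GLSZM zones are 8-connected; GLDM counts
Chebyshev-1 neighbours with exactly equal level (α = 0); NGTDM
excludes the centre pixel from the neighbour mean and drops pixels
with no in-ROI neighbour.

First-order statistics (mean, variance, skewness, Pearson kurtosis
(= excess + 3), median, percentiles with linear interpolation, IQR,
MAD, robust MAD on the 10–90 percentile subset, energy, RMS, min, max)
are computed on the continuous pre-discretization ROI values; Entropy
and Uniformity on the discretized histogram with log base 2. This is
why bin-width variation leaves the 14 statistical features (and the 9
shape features) exactly unchanged — the structurally forced ICC = 1 /
CV = 0% result.

Shape features use physical units: pixel surface (count × pixel
area), mesh surface and perimeter from the marching-squares 0.5-level
contour of the padded mask (holes subtract, so an annulus is handled
correctly), sphericity 2√(πA)/P, principal-axis lengths 4√λ from the
population covariance of pixel centres, elongation √(λ_min/λ_max),
and maximum diameter as the largest pairwise distance between pixel
centres (via the convex hull).

**Undefined values.** A formula that would divide by zero or take
log 0 as a whole (GLCM correlation at zero variance, Imc1 with
vanishing marginal entropies, NGTDM coarseness/busyness/strength on a
constant ROI, axis features of a single-pixel ROI) returns NaN, is
written as an empty CSV field, and is removed listwise per ICC matrix
— never silently zeroed. NGTDM contrast with a single occupied level
is defined as 0. Imc2's radicand is clamped at 0 against floating
point cancellation.

## Statistics

* **ICC**: two-way crossed ANOVA without replication on the complete
  n×k subject-by-condition matrix; the absolute-agreement single-rater
  form above. An all-identical matrix (0/0) is defined as ICC = 1 with
  a degeneracy flag, resolving the forced case deterministically.
  Negative estimates are reported as computed and banded "high".
  Band boundaries (0.5/0.75/0.9) belong to the lower band.
* **CV**: sample SD (n−1) over |mean|, ×100. Exactly 0 when all
  values are equal (guarded against 1-ulp mean round-off); undefined
  (NaN) when the mean is 0. Summaries are medians over subjects ×
  fixed conditions, dropping undefined records.
* **rmcorr**: within-subject centring of x and y (algebraically
  identical to the subject-dummy ANCOVA), common slope b,
  r_rm = sign(b)·√(SS_slope/(SS_slope+SS_err)), df = N − S − 1
  (= N(k−1) − 1 balanced), two-sided p from the t distribution.
  Refuses single-subject input and zero within-subject x-variance.
* **Bonferroni**: significant iff p ≤ α/m; the family m is all tests
  performed for one modality × effect (features × fixed conditions).
  The correction scope is a genuine convention choice; the adjusted
  p-values (`min(1, p·m)`) are also reported so other scopes can be
  recovered from the output tables.

Effect A and effect B are two slicings of the same 7 × 9
voxel-by-bin-width feature grid, which is extracted once per subject.
Effect C's rater set is the 7 filtered maps; including the unfiltered
map as an 8th rater is exposed as a config switch (default off).

## Problem sizes and verification

The default study conditions are 26 subjects, the 7 × 9 preprocessing
grid and 7 filters per modality. The test suite runs smaller cohorts
(2–10 subjects, sub-grids) for unit and property tests and the full
26-subject effect-B analysis in the acceptance tests; the acceptance
script uses 26 subjects. Matrix builders are verified exactly against
loop-based enumeration oracles on random small ROIs; ICC against a
sum-of-squares oracle and an independent statistics package
(pingouin); rmcorr against a least-squares ANCOVA oracle and
pingouin; the resampler against an independent B-spline evaluator;
feature formulas against independent loop transcriptions.

## Known limitations

* 2D only; no 3D feature variants or through-plane effects.
* No intensity re-segmentation, outlier filtering or denoising (none
  are part of the modelled pipeline).
* The wavelet sub-band naming convention (which axis the first letter
  refers to) differs between toolkits; rotation-consistency of the
  four sub-bands is tested, but cross-toolkit label alignment is not
  guaranteed.
* The stationary wavelet transform uses periodic (wrap) boundary
  handling; ROIs near the grid edge would see boundary artefacts
  (the default ring geometry keeps the ROI central).
* ICC confidence intervals are not computed.
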