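# Methods

This note documents the models, parameters and numerical choices behind
`autoprofiler`, and what the synthetic-data tests do and do not demonstrate.

## Reporter model and channel logic

The package targets two-channel time-lapse data from a tandem
pHluorin-mKate2-LC3 reporter. LC3 decorates autophagic vesicles; pHluorin
(GFP channel) is quenched at low pH while mKate2 (TRITC channel) is not.
Autophagosomes (AP) therefore fluoresce in both channels and autolysosomes
(AL) — after fusion with the acidic lysosome — in TRITC only. Detection
reduces to set logic on per-channel puncta masks: a TRITC punctum sharing at
least one pixel with the union of GFP puncta is an AP, the remaining TRITC
puncta are ALs, and GFP-only detections (candidate fast-moving
autophagosomes) are recorded but counted in neither class. The partition
identity |AP| + |AL| = |TRITC puncta| holds by construction and is asserted
in tests.

## Image processing

**Background correction.** Rolling-ball subtraction with a ball radius of
0.98 um (default pixel size 0.25 um/px, so ~3.9 px), via
`skimage.restoration.rolling_ball`. The background is bounded above by the
image, so corrected frames are non-negative. The operation is exactly
idempotent on flat fields but only approximately so on sloped structure: the
ball leaves a slope-dependent residual of a few percent of the dynamic range
that a second pass removes. Tests assert the bounded, monotone form of the
property.

**Spot detection.** Candidate seeds are local maxima of a
difference-of-Gaussians band-pass at the spot scale (0.8 um FWHM by
default). The commercial software whose workflow this mirrors exposes an
undocumented "contrast" unit with thresholds 5 (GFP) and 6 (TRITC); here
contrast is defined as (seed peak − local annulus background) / robust noise
SD of the corrected frame, a dimensionless SNR-like score in which those
printed defaults act as thresholds. Two numerical choices matter:

* the annulus background uses the **75th percentile** of an annulus at
  0.75–1.5 spot diameters. An isolated punctum barely raises that quantile,
  but an elongated ridge — the residual the rolling ball leaves along steep
  cell edges — passes through the annulus and raises it, suppressing edge
  artifacts without a separate shape filter;
* the robust noise SD is 1.4826 x the median absolute deviation of the
  corrected frame about its median.

Accepted seeds are grown ("grow bright regions") while intensity stays
above 50% of the seed value, bounded at 3x the spot diameter, capturing
puncta of different sizes with bounded support. The mapping from this
contrast definition to the commercial unit is calibrated on synthetic
scenes, not claimed identical.

**Segmentation.** A deliberately simple fallback — Gaussian smoothing,
Otsu threshold floored at median + 3 robust SD (so pure-noise frames yield
no cells), small-object removal and a distance-transform watershed. Label
masks from a trained segmenter can be supplied externally and bypass this
stage entirely.

**Tracking.** Greedy one-to-one bipartite matching on mask IoU between
consecutive frames, highest IoU first, matches below 0.3 rejected
(configurable; frame intervals of ~30 min are short relative to cell
motility). At a division the daughter with the larger IoU keeps the parent's
track id; the other daughter — and anything overlapping it later — is
discarded from the output rather than starting a new track. This loses data
by design but keeps every surviving track a single cell. Track ids are
stable under appending frames.

## Feature catalogue (949 features)

Each object (cell or vesicle) contributes 72 base features: 10 structural
(area, perimeter, eccentricity, axis lengths, solidity, extent, orientation,
circularity, aspect ratio), 9 intensity (mean/min/max/median/SD/integrated,
quartiles, range), 28 texture and 25 Zernike magnitudes. Whole-cell rows add
11 cell-only features (frame-to-frame centroid displacement, bounding-box
fill, edge contact, equivalent diameter, Euler number, convex area, max
Feret diameter, perimeter/area, intensity CV, radial intensity ratio, dark
area fraction). Per-vesicle features are aggregated with six descriptive
statistics (mean, 25%, 50%, 75%, max, min; linear-interpolation quartiles),
and the two counts `AP_number`/`AL_number` are appended:

    6 x 72 x 2 + (72 + 11) + 2 = 949

Whole-cell and AP features are measured on the GFP channel (better SNR), AL
features on TRITC. The exact name list of the original workflow lives in an
external repository; this catalogue fixes the cardinality, tags and
construction rules, not name-for-name equality.

**Texture.** Gray-level co-occurrence matrices at distance 1 in the four
2-D directions, object intensities quantised to 64 levels over the object's
min–max (stabilises the statistics for small puncta; configurable). All 14
classical Haralick statistics are computed, including the maximal
correlation coefficient (set to the undefined marker when numerically
singular), and summarised by mean and range over directions. Single-pixel
objects are undefined.

**Zernike moments.** Magnitudes of the 25 (n, m) moments with
0 <= m <= n <= 8, n − m even, over the binary mask in a disk of radius
0.5 x major axis length about the centroid, weights normalised by pixel
count. Magnitudes are rotation-invariant (checked to 1e−6 under 90-degree
rotation).

**Missing values.** A cell with zero vesicles of a class has that class's
aggregates set to NaN ("paper-mimicking" mode, in which downstream
NaN-column removal drops them — removal is always column-wise, never
row-wise) or to 0 ("imputing" mode). Per-vesicle NaNs (e.g. a singular
texture statistic) are ignored inside aggregation while at least one
vesicle has a value.

## Standardization and selection

Every feature is standardized per plate against the vehicle control:
z = (x − median(X_DMSO)) / (1.2532 x MAD(X_DMSO)), where MAD is the *mean*
absolute deviation about the DMSO median — for normal data
1.2532 ~ sqrt(pi/2) makes the denominator a consistent SD estimate (the
suite verifies SD/MAD of 10^6 normal draws falls within 0.4% of 1.2532).
Features with zero DMSO MAD are excluded with a warning. A feature is
significant for a treatment at a timepoint when |median z| >= 0.5 AND the
Benjamini–Hochberg-adjusted two-sided Mann–Whitney p against DMSO is
below 0.05. The BH family is all features at one (treatment, timepoint),
matching the per-timepoint volcano presentation; pooling timepoints into one
family is a sensitivity variant not enabled by default. The Mann–Whitney p
is exact (full enumeration) for pooled n <= 12 without ties, otherwise the
normal approximation with continuity and tie correction. The conjunction
rule is the false-positive control: on zero-effect tables (900 features,
300 cells/arm) the median significant-feature count over 20 replicates is 0.

## Classification and attribution

Cells' selected features are concatenated over all timepoints (one row per
tracked cell) — per-timepoint rows are also supported. Columns correlated
at |Pearson r| >= 0.75 with an already-retained column are dropped in
catalogue order (collinearity distorts importance estimates), zero-variance
columns first. The classifier is a 1000-tree random forest with the entropy
criterion, evaluated by stratified 5-fold cross-validation (stratification
guarantees class presence per fold at small n) scored with micro-F1; one
seed controls folds and forest and is echoed in the report.

Shapley attributions use the path-dependent tree algorithm (the
polynomial-time recursion over decision paths with cover-weighted
expectations), implemented here directly and numba-compiled; a brute-force
subset-enumeration oracle over each tree's used features is provided for
verification and agrees to ~1e−16 on small ensembles. Local accuracy
(base + sum of attributions = predicted class probability) is asserted at
1e−6. Multiclass rankings use mean |phi| summed over classes. Group
importance aggregates mean |phi| per entity x type group plus a
vesicle-number group: cumulative = sum over members, average = mean, so
cumulative = average x group size.

## Profiles, similarity and the standard curve

A treatment profile is the concatenation over timepoints of per-feature
medians of standardized values across the treatment's cells. Profile
similarity is the Pearson correlation with the reference treatment's profile
(default reference: 100 nM rapamycin) over the shared (feature, timepoint)
index, computed either over all selected features or over vesicle numbers
only. Hierarchical clustering of profiles uses average linkage on Euclidean
distances. The low-dimensional embedding is a Fisher discriminant (largest
eigenvectors of the between- over within-class scatter pencil, optional
ridge shrinkage for singular scatter), deterministic up to a fixed sign
convention.

The standard curve is an ordinary least-squares regression of normalized
cargo degradation (externally measured, expressed relative to the reference
treatment) on profile similarity. The plotted band is the mean-response 95%
CI; predictions for new treatments carry the 95% prediction interval, and
similarities outside the training range are flagged as extrapolation. The
slope CI was verified exactly calibrated: coverage 0.951 +/- 0.002 over
20,000 simulations, identical to the textbook t-interval. Acceptance checks
run 2,000 replicates so the Monte-Carlo error on the coverage estimate is
small relative to the 93% bound being asserted.

## Synthetic data: what it shows and what it does not

The generator renders cells as low-order Fourier-perturbed ellipses with
per-cell brightness, optional dark voids (wortmannin-like), per-hour
multiplicative intensity trends (rapamycin-like dimming), Poisson-distributed
AP/AL puncta rendered as 2-D Gaussians (FWHM = 0.8 um) placed uniformly in
the cell, AP in both channels and AL in TRITC only, plus additive Gaussian
noise (Poisson shot noise optional). Cell bodies are blurred with a
PSF-like Gaussian (sigma 0.75 um) — without it the hard cell edge is an
artifact no real microscope produces and its rolling-ball residual dominates
spot detection. Default pixel size is 0.25 um/px so a 0.8 um punctum spans
~3.2 px; image size, frame interval (0.5 h) and magnification are not fixed
by any published value and are preset fields. Divisions can be injected as
mask-splitting events with lineage recorded. Identical preset and seed give
bit-identical stacks.

The feature-table generator bypasses imaging and draws per-feature Gaussian
nulls with per-treatment shifts stated in robust-SD units, which is what the
power, specificity, classifier and similarity analyses consume.

Passing tests on this data demonstrate the pipeline's internal correctness
(detection against ground truth, selection specificity and power, attribution
exactness, curve calibration) — not performance on real microscopy, which
has textured cytoplasm, uneven illumination, focus drift and vesicle motion
that the generator deliberately omits.

## Problem sizes used in the acceptance run

Catalogue checks are exact; the scale-constant check uses 10^6 draws;
Mann–Whitney enumeration uses 200 5-vs-5 datasets; null specificity uses 20
replicates of 900 features x 300 cells/arm; planted-effect recovery uses 3
treatments x 300 cells x 3 timepoints with a 1000-tree forest and Shapley
attribution on 60 cells; detection fidelity uses 20 spots at SNR 10;
coverage checks use 2,000 slope simulations and 360 hold-one-out
predictions; the nine-treatment similarity panel uses 80 cells/arm x 2
timepoints with cargo driven by 30 morphological features and saturating
vesicle counts.

## Known limitations

* The contrast unit is a calibrated stand-in for an undocumented commercial
  quantity; absolute threshold equivalence is not claimed.
* The built-in segmenter assumes bright cells on dark background; real data
  should use externally supplied masks from a trained segmenter.
* Discarding the second daughter at division loses lineage data by design.
* Rolling-ball subtraction is only approximately idempotent on sloped
  structure (see above).
* Features of GFP-only ("fast-moving") puncta are not extracted.
* UMAP embeddings are intentionally out of scope; the Fisher discriminant is
  the tested embedding.
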