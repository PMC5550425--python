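# Methods

This note documents the models and procedures implemented in `blastograde`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Image standardization

Every stage downstream assumes an 8-bit greyscale raster of 1024 × 1280
pixels (rows × cols), the capture geometry for which the fixed pixel
offsets of the segmentation stage are meaningful.  Standardization is:

* RGB → grey by BT.601 luma weights (0.299, 0.587, 0.114), rounded
  half-away-from-zero (the rounding convention used throughout).
* Isotropic bilinear scaling so the image fits the canonical frame,
  centre-padded with the median border intensity (a hard pad edge would
  create spurious gradient energy at detection time).
* Linear contrast stretch mapping the 1st percentile → 0 and the 99th →
  255, clipping outside.  The percentile pair is a deliberate compromise:
  it makes texture quantization bins well-populated for any exposure while
  keeping the map robust to a few dead/saturated pixels.  A constant image
  cannot be stretched and passes through with a warning.

Standardizing an already-standardized image moves no pixel by more than
one grey level (the stretch endpoints are already at 0/255).

## Embryo circle and region masks

The embryo is localised from a smoothed (σ = 2 px) gradient-magnitude map.
The gradient magnitudes are square-root compressed before Otsu
thresholding: the inner-cell-mass rim produces gradients an order of
magnitude stronger than the zona pellucida flanks, and without compression
Otsu tracks those few strong edges and drops the boundary.  The binary map
is closed (disk radius 5), hole-filled, and the largest connected
component taken; its centroid is the centre and its equivalent-circle
radius `sqrt(area/π)` the embryo radius — preferred over a max
centre-to-boundary distance, which zona irregularities inflate.  Both are
reported at integer pixel precision so that a pure translation of the
image translates every derived mask exactly rather than re-rasterising it
with sub-pixel jitter.

Region masks (pixel-centre membership, Euclidean distance ≤ radius):
ER = circle + 5 px, RR = circle − 40 px, TE = ER ∖ RR (a 45 px annulus).
These offsets are configuration constants of the canonical resolution, not
adaptive quantities.  Radii ≤ 40 px are rejected (`RR` would be empty).

## Texture statistics

Intensities are requantized to 8 equal-width levels (`floor(v/32)`), then
a grey-level co-occurrence matrix is accumulated over all ordered pixel
pairs at distance d = 1 for the four standard angles (0°, 45°, 90°, 135°),
counting a pair only when **both** pixels lie in the region mask,
symmetrised and normalized.  The co-occurrence machinery is implemented
here rather than taken from a library because the both-ends-in-mask rule
over arbitrary masks is not expressible with the common array-level GLCM
routines; a brute-force pair-enumeration oracle in the test suite pins the
implementation exactly.  Statistics: contrast, correlation, energy
(angular second moment) and homogeneity.  A region with zero intensity
variance has undefined correlation; it is defined as 1 so feature vectors
stay finite.  Angle averaging makes the statistics invariant under 90°
rotations, which the suite checks.

## Watershed and the inner cell mass

The intensity surface restricted to the ER mask (dark = deep, i.e. basins
are computed on intensity directly, not on a gradient image) is smoothed
with σ = 2 px and its minima shallower than h = 4 grey levels are
suppressed (h-minima by morphological reconstruction) before flooding.
Without suppression, sensor noise shatters the region into thousands of
one-pixel basins; σ and h are exposed as arguments.  The basin count after
suppression is the WSN feature; the largest basin is the ICM mask — the
ICM being a comparatively homogeneous dark region, it forms the deepest
wide basin in well-formed embryos.  ICM descriptors: solidity (area /
convex hull area), moment-ellipse eccentricity, mean intensity.  In
degraded (grade-3) embryos the largest basin may fail to coincide with the
anatomical ICM; the resulting noisy shape descriptors are part of the
signal the classifier sees, not an error state.

## The 36-variable roster

For each region ER/RR/TE: GLCM correlation, energy, homogeneity, plus
mean, mode (ties → smallest level), "mean count" (pixels within ±5 grey
levels of the region mean) and "bright" (pixels ≥ 200) — 21 variables;
GLCM contrast for RR and TE — 2; the TE annulus split into four equal-width
concentric sub-rings with `Ck` = count of pixels darker than the ER mean
(C1 outermost) and `Mean Ck` — 8; `Sum` = total ER intensity — 1; WSN — 1;
and the three ICM descriptors.  The ±5 tolerance, the 200 grey-level
bright threshold and the equal-width sub-ring rule are this package's
normative definitions (module constants, isolated so they can be swapped);
`Contrast ER` is excluded so the grid completion lands on exactly 36.
The 24-variable pruned schema is fixed by name in
`features.SURVIVING_24` and is the default model input schema, making
trained model files portable across datasets; recomputing the pruning on
new data is available (`refit_vif`).

## Collinearity pruning

`VIF_i = 1/(1 − R_i²)`, with `R_i²` from an OLS regression (with
intercept) of variable *i* on the rest.  Elimination removes the single
largest-VIF variable per iteration (ties → earlier canonical order) until
all VIFs ≤ 10, the conventional collinearity threshold.  Variables are
z-scored before regression purely for conditioning — VIF is invariant to
affine rescaling.  Exact collinearity (R² within 1e−12 of 1) reports ∞.
The iteration count reported includes the terminal all-clear pass.

## Network engine

Architecture space: 1–3 hidden layers of 10–120 neurons, per-layer
transfer functions from {logsig, purelin, tansig, hardlim, tribas, radbas,
satlin}, a 3-unit output layer, one-hot grade targets, mse loss (mean over
all units and samples), full batch.  Inputs are min-max scaled to [−1, 1]
with training-partition bounds.  Data are split 70/15/15
(train/validation/test, round-down for the two 15% parts) by a seeded
permutation.  Training stops at 1000 epochs, after 6 consecutive
validation-mse increases (best-validation weights restored), or when the
gradient norm falls below 1e−7.

Five classic trainers are implemented on a flat parameter vector:

* `traingdm` — gradient descent, learning rate 0.01, momentum 0.9;
* `traingdx` — the same with multiplicative rate adaptation (×1.05 on
  improvement; step rejected, rate ×0.7, momentum reset when the mse
  rises by more than 4%);
* `trainrp` — Rprop+ (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.07, Δmax = 50) with
  per-weight backtracking on a gradient sign change.  Because step sizes
  adapt on gradient *sign* only, a transient one-epoch overshoot of the
  loss is possible by construction; the backtracking undoes it within a
  few epochs, which is the property the suite asserts (a strictly
  monotone loss is not attainable for this family of algorithms);
* `trainscg` — Møller's scaled conjugate gradient (σ = 5e−5, λ₀ = 5e−7);
* `traincgf` — Fletcher–Reeves conjugate gradient with an Armijo
  backtracking line search and periodic restarts.

`hardlim` is non-differentiable and propagates zero gradient; hidden
layers using it simply train poorly and are selected against by the
architecture search — no special casing.  Prediction is the argmax of the
three output activations, ties resolved toward the better (lower) grade.
Models serialize to JSON (genome, weights, scaling bounds, variable
names, seed, per-epoch record) and round-trip bit-identically.

## Genetic architecture search

Individuals are 9-gene genomes (three neuron counts, three hidden transfer
functions, output transfer, trainer, number of active hidden layers; genes
beyond the active depth are carried but inert so crossover can exchange
them).  Per generation: sort by fitness (classification accuracy of the
trained network on the configured partition), copy the top 10% unchanged,
build 60% as offspring of fitness-proportional (roulette) parents by
uniform per-gene crossover with 5% per-gene mutation (a mutated gene is
resampled uniformly from its domain), and fill the remaining 30% with
fresh random genomes; fractional counts are reconciled by the largest
remainder so the population size is exact.  Fitness is cached by genome,
which makes elitism exact: the best-of-generation fitness is
non-decreasing for every seed.  "5% mutation" is interpreted as per-gene
probability; per-individual probability and perturbation magnitude were
the alternatives and either would be a one-line change.

Scoring fitness on the *test* partition follows the original protocol but
leaks the test set into architecture selection;
`fitness_partition="validation"` is provided and recommended when the test
partition must remain a blind hold-out.

Default desk-scale profile: population 20, 30 generations, fitness
training capped at 60 epochs — sized so the full synthetic study (below)
runs end to end in minutes on one core.  The full-scale profile
(populations 100–300, 1000 generations, uncapped epochs) is reachable
through configuration and is a long-running mode.

## Evaluation battery

The reference grade of an image is the mode of its three rater grades;
the all-different case (1,2,3) returns the median 2, the only
order-symmetric resolution.  The confusion matrix reports total success,
per-class success and the serious-error rate (|reference − predicted| ≥ 2,
i.e. grade-1/grade-3 confusions); percentages are exact internally and
rounded to one decimal only for display.  One-vs-rest ROC curves and
trapezoidal AUCs come from scikit-learn behind the module surface; a
brute-force positive/negative pair-comparison oracle pins the AUC in the
tests.  Multi-rater agreement uses Fleiss' kappa (statsmodels) with the
Fleiss (1971) large-sample null variance for the z-test; pairwise
test–retest agreement uses Cohen's unweighted kappa.  A table in which
every rating is the same single category has expected agreement 1; kappa
is reported as 1 with a warning.

## Ensemble classification

`classify` runs an image through three trained networks and returns each
network's three raw output scores (the grade "histogram") plus a
consensus: the majority grade, or — when all three disagree — the grade of
the network with the largest margin between its top two scores, with the
rule that fired recorded in the result.  A graphical interface would leave
the three-way disagreement to the user; a command-line tool must decide,
and the margin rule picks the most confident network.

## Synthetic micrographs

The generator emulates the statistical structure the pipeline assumes in a
bright-field micrograph of an expanded blastocyst: a background of mean
grey 180 with a random-direction linear gradient (amplitude 18) and
Gaussian noise (σ = 6); an embryo circle (radius 180–260 px, jitter ±40 px
about frame centre) bounded by a bright zona shell (Gaussian ridge,
amplitude 42, σ = 5 px, planted just inside the boundary so the planted
radius marks the embryo's outer extent); a trophectoderm band of dark
cell-profile blobs; a lighter mottled blastocoel (the mottling gives the
watershed several shallow interior basins, as real cytoplasmic texture
does); and a single dark eccentric elliptical ICM.  Grade is encoded by
continuous degradation knobs drawn around the nominal grade (jitter
σ = 0.3 grade units, so the classes genuinely overlap): from grade 1 to 3
the ICM radius fraction falls 0.40→0.25 of the embryo radius and its
interior brightens 88→148, trophectoderm blobs become fewer, larger and
fainter, and the outline wobble grows.  All randomness flows from one
seed; identical parameters give bit-identical PNGs.

What passing tests show: the pipeline recovers planted geometry (median
radius error ≈ 2%, grade-1 ICM Dice ≈ 0.8), the features separate the
planted grades, and the search/training machinery can exploit them
(held-out accuracy ≈ 95–98% at desk scale — the synthetic classes are
easier than real embryo grades, where expert raters themselves disagree).
What they do not show: performance on real micrographs, with debris,
hatching embryos, off-centre framing, optical artefacts, or the
borderline morphologies that drive human disagreement.  The generator
makes no attempt at photorealism or at modelling microscope optics.

## Study sizes used by the test suite

The acceptance-style tests run a 300-image study (100 per grade, seeds
0–299) through the full pipeline once per session, then a population-20 ×
30-generation search on its features; statistical calibrations use
n = 500 rating tables and 16 × 16 texture oracles.  These sizes were
chosen as the smallest at which the checked properties are stable across
seeds.
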