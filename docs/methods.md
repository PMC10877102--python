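# Methods

## Pipeline model

The unit of acquisition is a pair of calibrated single-channel Z-stacks
(DAPI = nuclei, 53BP1 = foci) from one location of an *ex vivo* tumor
slice. The analysis assumes (i) one focal plane per image captures a
representative nuclear cross-section (tissue nuclei overlap in depth, so a
full-stack projection would merge them); (ii) foci are punctate and bright
relative to their surroundings, with some signal one plane above/below
focus; (iii) a focus belongs to the nucleus whose segmentation contains
it. The headline readout is foci per nuclear volume,
`count / (area × projection height)`, in foci/µm³ — the projection height
is the number of slices actually projected times the z-step, so clamping
at a stack edge shrinks the denominator honestly rather than silently
assuming three slices.

Plane selection uses the arithmetic mean over all pixels (background
included) of each DAPI plane; ties break to the lowest index. The foci
projection window is clamped at stack boundaries rather than shifted or
padded — clamping keeps the operation total and the recorded height
matches the planes actually used.

## U-net

Both channels share one architecture: depth-4 encoder–decoder with skip
connections, two padded 3×3 convolutions per level (batch norm after each
convolution, before ReLU), 2×2 max pooling, nearest-neighbor upsampling
followed by a 3×3 convolution, base 16 filters doubling per level, 1×1
sigmoid head. Per-image min–max normalization to [0, 1] precedes the first
layer so the net is exposure-invariant (tissue images vary widely in
staining intensity by design). The architecture specifics the recipe does
not pin down — depth, filter counts, padding, binarization threshold 0.5,
and min–max (rather than standardization) normalization — are this
package's documented choices, exposed through `UnetConfig`.

Training minimizes the soft Jaccard loss (ε = 1e-6) with Adam
(lr 1e-3, β = 0.9/0.999), one of the 8 dihedral transforms plus a contrast
factor drawn from {0.8, 1.0, 1.2} per sample (darkening unrestricted,
brightening saturated at the image maximum — a pure scalar multiply would
be cancelled by min–max normalization), and keeps the weights of the epoch
with the lowest validation loss (first minimum on ties). Nuclei mode
resamples images bilinearly and masks by ≥ 0.5-coverage binarization to a
fixed input size (512×512 full scale; batch 32, 200 epochs); foci mode
keeps native resolution (batch 8) and reflect-pads inputs to a multiple of
2^depth at prediction time. The full recipe is available through config;
tests and the acceptance script train a reduced recipe (20 epochs, 20
pairs of 128×128 scenes, batch 4) sized for a single CPU.

The layers are implemented directly on numpy (im2col convolutions backed
by BLAS matmul, float32) with a hand-written backward pass and Adam; a
seeded run is reproducible on one device.

## Instance post-processing

Hole filling → watershed → exclusion, in that order. "Tolerance 4" is
interpreted as prominence on the Euclidean distance transform: markers are
the regional-maximum plateaus of the morphological reconstruction of
(distance − 4) under distance, so twin peaks separated by a saddle
shallower than 4 px merge into one marker (one nucleus), while deeper
saddles split. Note that thresholding the reconstruction residue at h —
the textbook h-maxima shortcut — keeps equal-height twin peaks separate
regardless of their saddle and over-segments; the plateau construction is
the correct prominence semantics. The watershed floods the inverted
distance map inside the mask with single-pixel background split lines, so
the union of instances is a subset of the input foreground. Exclusion
removes objects touching the outermost pixel frame and objects below
10 µm² at the acquisition pixel size (183.65/1024 ≈ 0.17935 µm/px:
a 200 px object is 6.43 µm² and is removed; 400 px is 12.87 µm² and kept).
Post-processing runs at full resolution so the physical-area threshold is
applied at the declared scale. Survivors are renumbered 1..K in original
order. Connected components are 8-connected everywhere; coordinates are
0-based (row, col); centroids are unweighted pixel-coordinate means.

## Quantification and evaluation

The foci mask is intersected pixelwise with the nuclei label map; each
8-connected component of the intersection is one focus, assigned to the
majority nucleus label (ties to the lower id), clipped rather than
discarded when it straddles a boundary. Nuclei with zero foci are kept
with density 0. Focus size is emitted both in µm² and px, since the
field's "focus size" convention is ambiguous between the two.

Pixel metrics count TP/FP/FN over pixels; both-empty masks score
DSC = IoU = 1 by convention. Object DSC matches component centers
one-to-one by optimal assignment (maximize matches, then minimize total
distance) among pairs strictly closer than 3 px — optimal rather than
greedy matching makes the metric well-defined and symmetric under swapping
prediction and truth. Agreement between predicted and ground-truth
per-image values is OLS with R² equal to the squared Pearson correlation,
with standard errors on slope and intercept. When the foci net is
evaluated objectwise on synthetic scenes, the prediction is first
restricted to the nuclei interior (the pipeline's overlay step): the
generator deliberately renders extranuclear speckle without ground-truth
entries, and the pipeline never counts foci outside nuclei, so the
overlaid prediction is the quantity the method actually uses.

## Condition statistics

Per patient, per-nucleus densities (or per-focus sizes) are pooled across
the images of each condition — individual nuclei are the unit of analysis,
with per-image summaries additionally emitted for plotting. The omnibus
test is Kruskal–Wallis with tie correction (H = 0, p = 1 when all values
are identical); with ≥3 groups and p < α, Dunn's z-tests on the pooled
ranks follow with Bonferroni adjustment (the most common Dunn pairing;
configurable in principle, Bonferroni is the only adjustment implemented).
Intra-tumor intra-condition variation is 100 × sample SD (n−1) / mean of
per-image values; the per-image summary is the mean of the variable (a
median variant is also available). Both rank tests are implemented from
their rank formulas and cross-checked in the test suite against scipy
(Kruskal–Wallis, paired t), statsmodels (OLS) and an independent rank
computation (Dunn).

## Synthetic scenes

The generator emulates the acquisition regime: nuclei are random ellipses
(radius ~ N(3.4, 0.6) µm, axis ratio up to 1.3²) with per-nucleus
amplitude variation, a radial profile dimmed by 30% at the center
(mimicking reduced DAPI signal in nuclear centers), DAPI decaying by 0.55
per plane away from the focal plane, constant background 20 and Gaussian
noise SD 8 per plane. A quarter of nuclei are placed touching or
overlapping a neighbor; ground truth keeps overlapping nuclei as distinct
labels while the rendered image merges them — exactly the clustering the
watershed must resolve. When overlap is disabled the generator enforces
clear separation so instance recovery is exact by construction. Placement
is sequential rejection sampling; an unplaceable geometry draw (too large
for the remaining space) is redrawn a bounded number of times before the
generator errors, keeping generation reliable across arbitrary seeds at
the default density. Foci
counts are Poisson with mean `baseline (0.5) + dose × rate (2/Gy)`; foci
are uniform in the parent ellipse with their full 2σ footprint inside the
parent's ground-truth region and mutually separated so each ground-truth
focus is a distinct component (draws that cannot be placed after bounded
retries are skipped — at the default geometry the realized mean stays
within Monte-Carlo error of the Poisson mean, which the tests check).
Puncta are Gaussian (σ ≈ radius/1.4, radius ~ N(0.30, 0.05) µm), rendered
at 45% amplitude one plane off focus; ~10 extranuclear speckles per image
are rendered in the foci channel with no ground-truth entry. Cohorts give
each patient a lognormal sensitivity multiplier (log-SD 0.2) on the
foci-per-Gy rate.

Defaults are 256×256 px desk-scale scenes at the acquisition calibration
(12 nuclei/scene ≈ 190 per full 1024² field, within the 14–450 range
tissue images show); full-scale scenes are a parameter change. The
generator makes no claim of matching the real nucleus-density
distribution, confocal PSF physics, 3D focus structure, or
mitotic/apoptotic morphologies — passing tests demonstrate the pipeline's
correctness on images with known truth, not segmentation performance on
real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script use: 64–128 px scenes for training (20
training pairs, 20 epochs, ~2–3 CPU-minutes per net), a 3-patient × 2-
condition × 5-image gt-bypass cohort at 256², 200 simulations for the
type-I-error calibration (the null model draws per-nucleus densities from
the same Poisson model the renderer uses, skipping image rendering, since
the statistic under test consumes measurement tables). Degenerate inputs
are defined, not crashed: empty masks give zero objects, empty images give
NaN summaries, all-tied samples give H = 0/p = 1, and a both-empty metric
pair scores 1. The soft-Jaccard ε is 1e-6; batch-norm ε 1e-5; assignment
ineligibility is encoded as a cost exceeding any feasible total distance.

## Known limitations

No 3D foci measurement or intensity-weighted metrics; the watershed
tolerance is in pixels at the processed resolution (as in the original
FIJI workflow) and is not resolution-invariant; Dunn's adjustment is
Bonferroni only; training at the full 512×512/200-epoch recipe on CPU is
possible but slow (hours); the numpy backend trains small models well but
is not intended for large-scale experimentation.
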