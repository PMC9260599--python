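# Methods

## Pipeline overview

The package implements a weakly supervised feature-discovery workflow for
pathology slides. The only label used anywhere is one bit per slide
(effective / ineffective therapy response); no pixel- or patch-level
annotation exists at any stage. The stages are: gapless tiling, patch
quality control, unsupervised autoencoding, k-means feature formation,
per-cluster outcome scoring, key-feature selection, and slide-level
classification.

## Tiling

A slide raster is cut into a non-overlapping, gapless grid of
`patch_size` × `patch_size` cells (default 128), row-major, origins at
multiples of the patch size, 0-based with x = column and y = row. Partial
cells at the right/bottom edge are *emitted*, not dropped: the QC size
criterion rejects them downstream, preserving the original pipeline order
and making the rejection observable in the QC report. Pyramidal input is
supported in the form of multi-page TIFF (page = level); plain PNG/JPEG
rasters are treated as single-level slides. Dedicated whole-slide formats
(SVS et al.) are out of scope; any raster exported from a slide reader
works.

## Patch quality control

Four rejection criteria, evaluated first-cause in the order
size → blank → brightness → variance:

| criterion  | rule (defaults)                          | rationale |
|------------|------------------------------------------|-----------|
| size       | width or height < 128 px                 | edge tiles |
| blank      | ≥ 75 % of pixels near-white              | too little tissue |
| brightness | mean channel value < 120 or > 250        | too dark / bright |
| variance   | pooled channel variance < 80             | near-constant / contaminated |

"Blank" is defined as all three channels ≥ 240, the usual near-white H&E
background convention; the threshold is config. Brightness and variance
are computed over the flattened 3·N channel values on the 0–255 scale,
variance with ddof = 0 (population). Size runs first because edge patches
cannot be meaningfully scored and the check is free; a patch failing
several criteria is counted once, under the first. Filtering is
idempotent and order-equivariant, and raising the blank threshold can
only lower the blank-rejection count — all three properties are tested.

## Autoencoder

No deep-learning framework is required: the network is implemented in
numpy (im2col convolutions with manual backpropagation, Adam optimizer,
float32). The encoder is four stride-2 3×3 convolution blocks with ReLU
(3→8→16→32→32 channels, 128→8 spatial), whose flattened 8×8×32 = 2048
feature map is linearly projected to the `latent_dim` bottleneck (default
2048, i.e. a square projection). The decoder mirrors this: a dense layer
back to the conv feature size, then four nearest-neighbour-upsample +
stride-1 convolution blocks ending in a sigmoid. Resize-convolution was
chosen over transposed convolution because it needs only plain
convolution backprop and avoids checkerboard artifacts; the bottleneck
contract (a 2048-number code for a 128×128×3 patch) is unchanged.

The linear projection matters for reduced-dimension test configurations:
an earlier design made the bottleneck a 1-channel 8×8 conv map at
`latent_dim` = 64, which discards almost all color information and made
downstream clustering unstable; projecting the full 2048-d conv feature
keeps color and texture axes in any latent size.

Loss is mean squared error on pixels scaled to [0, 1]; optimizer Adam
with learning rate 1e-3; batch size 64; 50 epochs by default (tests and
the synthetic benchmark use 5 or fewer). A single seed drives weight
initialization and batch shuffling, giving bit-reproducible runs on the
same machine (pure-numpy arithmetic has no nondeterministic kernels).
Layers keep persistent scratch buffers, so steady-state training performs
no large allocations — this is a significant speedup on systems where
page faults are expensive. Checkpoints serialize weights plus config and
the per-epoch loss log; save → load → encode is bit-identical.

## Feature formation and scoring

Latent vectors are clustered with k-means (scikit-learn, k-means++ init,
10 restarts, fixed seed, lowest inertia kept). k defaults to the number
of distinct training slides, following the reference workflow (38 slides
→ 38 clusters). Any patch is assigned to the nearest centroid by
Euclidean distance; the one-hot indicator u has a single 1 at the argmin,
with exact ties broken toward the lowest cluster index (a measure-zero
event in floats, but defined for determinism). Assignment is checked in
tests against a brute-force nearest-neighbour scan and is invariant to
common rescaling of latents and centroids.

Scoring follows the rate calculus exactly: r₊ₖ and r₋ₖ normalize by the
total positive/negative patch counts over *all* clustered patches, so
Σₖ r₊ₖ = Σₖ r₋ₖ = 1 (tested as a conservation law). Iₖ = r₊ₖ/(r₊ₖ+r₋ₖ);
Wₖ = 1 + |0.5 − Iₖ| ∈ [1, 1.5]. Degenerate cases are defined explicitly:
a cluster with no labeled members gets Iₖ = 0.5, Wₖ = 1 and an `empty`
flag; an input whose patches are all one label is rejected (rates
undefined). Polarity at exactly Iₖ = 0.5 is "neutral".

Key features are clusters with Wₖ > `key_threshold` (default 1.1) whose
morphology is not "shape". Morphology normally comes from an expert
annotation table (cluster → shape | histology). When none is supplied, a
documented heuristic stands in: clusters whose members average more than
35 % near-white pixels are called "shape" — motivated by the observation
that tile-geometry clusters group by blank margins. The heuristic is a
fallback, not a claim of equivalence with expert reading.

The package ships the published 38-cluster reference table (impact
scores, sizes, morphology descriptions) as a worked example; applying the
polarity rule yields 25 positive / 13 negative features, 8 clusters
exceed W = 1.1, and excluding the two shape clusters leaves the key set
{33, 15, 9, 2, 27, 30}.

## Slide vectors and prediction

A slide's feature vector entry k is (fraction of the slide's QC-passed
patches assigned to cluster k) × Wₖ. Fractions, not raw counts, are used
because slides differ greatly in patch counts; with all Wₖ = 1 the
vectors reduce to occupancy histograms (tested). A slide with zero
surviving patches is an explicit error, never a silent zero vector.

Classifiers are scikit-learn logistic regression (max_iter 1000) and
linear SVM (C = 1). Cross-validation is stratified 10-fold with a fixed
shuffle seed; an optional `groups` argument switches to group-aware
stratified folds to prevent a patient's slides from straddling the
train/test split. Reported metrics: per-fold accuracy (mean/min/max),
pooled ROC and AUC over out-of-fold continuous scores (predicted
probability for logistic, decision-function margin for SVM), per-fold
AUCs, and a normal-approximation CI over folds (mean ± 1.96·sd/√n —
labelled as such; other CI constructions are defensible). A
`hard_label_roc` flag reproduces the degenerate ROC obtained from
predicted labels instead of scores, which some workflows report for
SVMs; continuous scores are the statistically standard default.

## Clinical score

Eleven oral sites × three lesion types (reticulation/patch,
erythema/congestion, erosion/ulcer), each scored 0/1/2 by affected area
(absent / ≤ half / > half). Total = Σ sites (reticulation + 1.5·erythema
+ 2·erosion), range 0–99. The response label is "effective" iff the
third-visit total is *strictly* more than 10 % below the first-visit
total (boundary reading: exactly 10 % is ineffective). A zero baseline
makes the relative change undefined and is rejected. The second visit is
accepted in input files but unused by the label.

## Synthetic cohorts and what they show

`histokey.synthetic` builds pseudo-slides from 128-px cells of procedural
texture classes: nucleus-like dark blobs on purple, oriented stripes on
peach, dark speckle on green, ring outlines on blue, plus a near-blank
class for QC tests. Class compositions are conditional on the slide
label; with equal patch totals per label, the impact score of the cluster
matching class c has closed form ρ_c = p_c/(p_c + q_c), where p, q are
the class probabilities on positive/negative slides. Defaults — 20
slides (10/10), 6×6 grid, positive composition (0.4, 0.3, 0.2, 0.1) vs
negative (0.1, 0.2, 0.3, 0.4) — give designed enrichments
(0.8, 0.6, 0.4, 0.2), spanning the range observed in the reference
cohort. All randomness flows from one cohort seed.

The parameter-recovery benchmark runs the full pipeline at reduced scale
(latent 64, 5 epochs, k = 4) and requires each matched cluster's
estimated I to fall within ±0.1 of its designed ρ, and cross-validated
accuracy ≥ 0.9; observed deviations are ≤ 0.05 across seeds. Problem
sizes were chosen so a single-CPU run finishes in a few minutes.

What passing these tests shows: the tiling/QC/encoding/clustering/scoring
machinery is mathematically correct, the latent space separates visually
distinct texture classes, and the score calculus recovers designed
associations from weak slide labels. What it does not show: performance
on real H&E tissue. The textures have no stain variation, focus drift,
nuclei morphology, or spatially correlated composition; real clusterings
are noisier, and the expert morphology step is replaced by an annotation
file or a blank-fraction heuristic. Headline clinical-cohort accuracies
are therefore not claims this package can certify.

## Numerical choices and limitations

- All thresholds (blank 240 / 75 %, brightness 120–250, variance 80,
  size 128, key threshold 1.1, response −10 %) are config with defaults
  matching the reference workflow.
- K-means on raw (unnormalized) latents, matching the workflow; no PCA
  or whitening beforehand.
- First minimum wins at argmin ties (numpy semantics), documented above.
- Autoencoder capacity is modest by design; it is a feature extractor,
  not a generative model. Reconstruction of fine pixel noise is not
  expected.
- Cross-validation at slide level by default; patient-level grouping is
  opt-in. With one slide per patient (the synthetic default) they
  coincide.
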