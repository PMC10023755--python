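# Methods

This note documents the models, parameters and numerical choices behind
`pwml`, and what the synthetic experiments do and do not establish.

## The task being emulated

Punctate white matter lesions (PWMLs) are small (≈1–5 mm), focal,
T1-hyperintense foci in infant periventricular white matter, often multiple
(1–19 per case, mean ≈ 6, SD ≈ 5.4 in the population the defaults emulate).
Detector training data are scarce, so the package builds composites: lesions
extracted from a couple of heavily affected source cases are pasted into
many normal slices.  Every stage below is deterministic given one user seed;
per-stage substreams are derived by hashing (seed, stage name, item index),
so inserting or re-running a stage never perturbs the others.

## Phantom (synthetic slice model)

A slice is two concentric ellipses — brain outline (semi-axes 0.40/0.34 of
the canvas, ±3 % jitter) and a cortical ribbon of fixed thickness (8 px) —
with two crescent-like ventricles flanking the midline.  Intensities follow
the neonatal T1 ordering: cortex (170) brighter than unmyelinated white
matter (120), CSF dark (50), air ≈ 12, all on the 8-bit scale, with a 1-px
Gaussian boundary blur standing in for partial-volume averaging and additive
Gaussian noise (SD 5, a typical 8-bit MR noise floor).  Pixel size defaults
to 0.83 mm.  The white matter forms a single 8-connected component interior
to the ribbon; because the ventricles are interior holes it is connected but
not hole-free.

Lesions are isotropic Gaussian bumps truncated at 2σ, added to the image.
The ground-truth mask is the > 0.25·peak level set (radius
√(2 ln 4)·σ ≈ 1.665 σ) and the ground-truth box is that mask's tight
half-open bounding box.  Mask diameters default to 2–6 px (≈1.7–5 mm at
0.83 mm/px); peak contrast defaults to 50 intensity units above local white
matter — a conspicuous focus, ≈10 noise SDs.  Lesions are placed by
rejection sampling entirely inside white matter with 3 px of depth margin
(`wm_margin`), mirroring the periventricular (not juxtacortical) location of
real PWMLs, and never overlap.  Per-case lesion counts can be drawn from a
rounded normal (mean 6.0, SD 5.4) clipped to [1, 19].  A "source case" is a
stack of independently generated slices sharing one seed lineage; the
reference configuration uses two cases with 19 and 17 lesions spread as
evenly as possible over 7 + 6 = 13 slices.

A note on a discretisation effect: the continuum mean of the truncated bump
over its own mask is 0.54·contrast, but for the smallest masks pixelation
overweights boundary pixels and the discrete mean can dip to ≈0.46·contrast;
tests assert the honest 0.45 bound.

## Intensity normalization

Both lesion-bearing and normal slices pass through a percentile-clipped
linear stretch before any compositing: with n pixels, the darkest
⌊clip_low·n⌋ and brightest ⌊clip_high·n⌋ values (0.1 % per tail by default)
saturate at the output bounds and the rest map linearly onto [0, 255],
re-quantized by round-half-away-from-zero.  For single-channel images this
is the behavior of interactive auto-contrast/auto-tone tools up to the
(unknown) clip settings, which are therefore exposed as parameters.  The map
is monotone, idempotent after quantization, and leaves constant images
unchanged.

## Lesion extraction

Extraction models interactive auto-selection with reproducible rules, in
two statistical passes plus a delineation pass:

1. **Robust candidate pass** — a pixel is a candidate when it exceeds the
   local median by `k_sigma` (3.0) robust SDs (1.4826·MAD), both computed in
   a sliding `local_window` (15 px).  Median/MAD are immune to the lesion's
   own pixels; a plateau-like lesion filling ~10 % of the window would
   otherwise inflate a mean/SD estimate enough to mask itself.
2. **Clean threshold pass** — background mean and SD are re-estimated
   excluding candidates dilated by 3 px, and the final threshold is
   mean + k_sigma·SD.  When a tissue map is available, statistics and
   candidates are restricted to white matter eroded by `boundary_margin`
   (3 px), skipping the partial-volume rim where cortex brightness bleeds
   into WM.
3. **Delineation** — each accepted component ("core") grows to the
   connected region of the 3×3-median-filtered image above
   background + 0.25·(median-peak − background): the tolerance semantics of
   region-based auto-selection, evaluated on a denoised field so single
   noise pixels neither join nor break the mask.  The level matches the
   phantom's 0.25-peak mask definition (the median filter attenuates center
   and flank of a multi-pixel blob almost equally, so no level adjustment is
   needed).

Inclusion rules then mirror the clinical reading criteria: area within
[`min_area`, `max_area`] = [3, 40] px (wider lesions are "widespread", the
area floor also rejects paired noise pixels, which at k = 3 occur at a rate
of ~0.1–0.5 per slice and are statistically indistinguishable from 2-px
lesions); elongation (√ of the principal second-central-moment ratio) ≤ 3
("linear" lesions excluded); peak-above-background ≥ `min_contrast` = 10
("faint" signals excluded); centroid in white matter.

Measured on the default phantom conditions (20 slices, 6 lesions each,
diameters 3–6 px), extraction recovers the injected lesions with precision
and recall of 1.0 under the fixed test seeds and ≈0.99–1.0 across arbitrary
seeds; an occasional single-pixel box offset on the smallest lesions is the
failure mode, which is why recovery is scored by mutual center containment
rather than box IoU (a 3×3 truth box flips across IoU 0.5 on one boundary
pixel).

## Compositing

Every lesion slice is paired with every normal slice — the full
cross-product, so 13 × 72 = 936 composites at the reference scale — and
each patch of the source slice is placed once per composite by rejection
sampling (≤100 attempts) under: white matter only, the entire patch
rectangle ≥ `margin` = 2 px from any non-WM pixel, no overlap between
pasted patches, and confinement to one of three equal-height
anterior-to-posterior bands of the WM extent, chosen by the
anterior-posterior rank of the patch's source centroid.  The bands are the
package's coarse stand-in for "frontal-to-parietal regions"; no atlas or 3D
registration is attempted.  Pasting is a direct mask copy with an optional
1-px feather (mask-boundary pixels take the patch/background mean); pixels
outside the mask are bit-identical to the background, so ground truth can
be recomputed from the difference image.

## Augmentation

The fixed op set is {identity, left-right flip, scale 0.95, scale 1.05,
rotate +15°, rotate −15°} — six outputs per input, the original retained.
Scale/rotation act about the canvas center with bilinear resampling, the
canvas size preserved (crop/pad, fill 0).  Boxes are mapped by transforming
their four corners with the same affine map and taking the axis-aligned
hull (standard practice for rotated boxes; it over-covers rotated content
slightly), then clipping to the canvas; boxes clipped below one pixel are
dropped with a logged warning.  Coordinates treat pixel (r, c) as the unit
square [c, c+1)×[r, r+1), so flips are exact mirror arithmetic and the
flip transforms are involutions.

## Annotations and split

Pascal VOC XML uses the labelImg dialect (1-based closed integer corners;
`xmin_voc = x_min + 1`, `xmax_voc = x_max` against the internal 0-based
half-open convention) — the round trip is exact.  YOLO darknet txt stores
normalized center/size with six decimals; corners survive the round trip to
within 1 px at 256 px.  Detections JSON carries percent confidences
validated in [0, 100].  The train/validation split is a seeded shuffle with
|train| = ⌊0.8·N⌋ (936 → 748/188).

## Reference detector

A deterministic classical stand-in so the evaluation loop runs end to end —
it is *not* a neural detector and its scores are not calibrated.  After a
0.8-px denoising blur, a scale-normalized Laplacian-of-Gaussian bank (blob
radii 1.5, 2, 3, 4 px; σ = r/1.665 so the detected scale matches the
phantom's mask radius) finds 3×3×scale local maxima, filtered by: a
SIFT-style Hessian edge rejection (tr²/det ≤ (r+1)²/r with r = 10 —
without it the bright cortex ribbon's ridge responses out-score every
lesion), an absolute response floor of 0.5 intensity units (above the
truncated-kernel bias a flat image produces), and an intensity gate at 20 %
of the image maximum (no detections centred on air).  Greedy NMS at
IoU 0.3 runs over the strongest 400 candidates.  Scores are
100·response/max-response-per-image — monotone in contrast but
uncalibrated; the per-image maximum is sometimes a cortex corner, in which
case lesion scores land in the 35–90 % range.

## Evaluation protocol

Matching is greedy one-to-one in descending confidence; a detection is TP
iff it satisfies the criterion with a so-far unmatched truth (ties broken
by largest IoU).  The default criterion is IoU ≥ 0.5; `center_in_box`
(detection box contains the truth-box center) is offered — and used for the
phantom experiments — because punctate truth boxes of 3 px flip across any
IoU cut on single-pixel differences.  With disjoint ground-truth boxes (the
compositor forbids overlap) a detection can satisfy IoU ≥ 0.5 with at most
one truth, so greedy matching attains the maximum matching; the tests check
this against exhaustive assignment search.  Sensitivity and PPV are pooled
over images per threshold {20, 30, 40, 50} %; TP+FN equals the lesion count
at every threshold and TP is non-increasing in the threshold (the ≥ t
detections are a prefix of the ≥ t′ list for t > t′).  PPV is reported as
missing (NaN), not 0, when no detection survives a threshold.

False positives are classified by majority tissue label among in-box
pixels, restricted to cortex vs white matter; ties go to cortex; boxes
containing neither label count as "other".  On phantom composites most
false positives are white-matter noise blobs rather than the
cortex-dominated pattern reported for trained CNNs on clinical data — the
phantom's cortex is too smooth to fool the Hessian edge filter, which is a
known gap between phantom and clinical behavior.

The Mann–Whitney U test uses midranks; when n₁·n₂ ≤ 400 and the pooled
sample is tie-free the two-sided p comes from the exact U distribution
(partition-counting recursion), otherwise from a normal approximation with
tie correction and 0.5 continuity correction.  Medians/IQRs use
linear-interpolation quantiles.  Average precision is single-class,
all-point interpolated (precision envelope).  scipy's implementation serves
only as an independent oracle in the tests.

## Problem sizes and limitations

The test suite and the acceptance script run the corpus arithmetic at the
study's printed scale (13 × 72 = 936 composites, 600 → 3600 augmentation,
936 → 748/188 split) and the stochastic stages at deliberately modest sizes
(20 recovery phantoms; a 60-image validation subset for the detector
sweep), sizes chosen to keep a full run on one CPU in the minutes range.

What passing these experiments shows: the construction arithmetic, geometry
handling, format round trips and scoring statistics are correct, and the
extraction rules recover known injected lesions exactly under the stated
conditions.  What it does not show: anything about real MR contrast, bias
fields, motion, 3D lesion continuity, or the absolute performance of a
trained CNN — the phantom has none of those, and the reference detector's
absolute sensitivity/PPV/AP values characterize the phantom conditions
only.  Known limitations: 2-px-diameter lesions sit at the noise floor at
k = 3 and cannot be recovered with guaranteed precision by any threshold
rule; the phantom's white matter is not hole-free; the augmentation's
axis-aligned hulls inflate rotated boxes by up to one pixel per edge.
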