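# Methods

This note documents the models, numerical choices, and open design
decisions behind `chdseg`, and what the phantom-based tests do and do
not demonstrate about clinical data.

## Label taxonomy and conventions

Seven foreground structures: LV=1, RV=2, LA=3, RA=4, Myo=5, Ao=6, PA=7;
background 0. Two auxiliary codes exist only in the 2D blood-pool stage
(interior=8, boundary=9). Venous structures follow the merge convention
common in CHD labeling: venae cavae carry the RA code and pulmonary
veins the LA code, because they are continuous with the atria and their
boundary is ill-defined on CTA. Anomalous vessels are coded as the
structure they connect to (an anomalous vein draining to RA is RA).

Volumes are `(z, y, x)` indexed, 0-based, with per-axis spacing in mm;
physical position = origin + index·spacing.

## Segmentation metrics and loss

* Dice = `2|P∩T| / (|P|+|T|)` per structure. Both-empty scores 1.0
  (structure correctly absent — CHD cases can genuinely lack one) and is
  flagged in reports.
* Combined loss = soft-Dice term (mean over classes) + cross-entropy
  term scaled by `1/(NC)`. The Dice ratio gets a smoothing constant
  1e-6 in numerator and denominator so classes absent from both
  prediction and truth contribute no penalty; probabilities are clamped
  to `[1e-7, 1]` before the natural logarithm so the loss is finite.

## Phantom generator

The generator emulates the *topological* variety of a CHD CTA dataset,
not its metric anatomy: four ellipsoidal chambers, a 4 mm myocardial
shell around the ventricles, and vessels swept as open tubes (no end
caps) along chord-length-parameterized cubic splines, rasterized at
0.5 mm arc steps. Label precedence chambers > vessels > myocardium keeps
the blood pool continuous across the valve planes. The default grid is
96³ at 1 mm isotropic — a desk-scale stand-in for 512×512×(130–340)
clinical grids chosen so the whole 20-case suite runs in minutes on one
CPU.

Intensities: blood pool 300, myocardium 150, background 0 (arbitrary
CT-like units, roughly contrast-enhanced blood vs muscle vs air/fat),
softened by a 0.6-voxel Gaussian blur (linear partial-volume stand-in)
plus additive Gaussian noise with σ=20 — a generous noise floor for
contrast CTA at these intensity separations. No beam hardening, motion,
or scanner artifacts are modeled: passing tests demonstrate the graph
machinery under correct-but-discretized segmentation inputs, not
robustness to clinical image quality.

Five topology variants cycle through the suite: `normal`,
`swapped_origins` (transposition-like: trunks swap ventricular origins,
distal courses kept, so the proximal segments cross),
`common_trunk` (single Ao-coded trunk with PA branches),
`anomalous_vein` (extra vessel draining to RA), and `sling` (LPA arising
from the RPA, wrapping posteriorly). Suite jitter: ±2 mm global shift,
±0.7 mm per-point noise, ±10% radius scale, seeded per case.

## Learned stages

Both U-nets are small encoder/decoder convnets implemented in numpy
(hand-written backprop, Adam): two 3³ (3D) or 3² (2D) convolutions per
level, leaky ReLU (slope 0.1 — a width-8 net with hard ReLUs can lose
whole feature channels early and never recover), average-pool down /
nearest-neighbour up, skip concatenation, 1-kernel softmax head. Default 2 levels with 8 initial
filters, doubling per level. Normalised voxel coordinates are appended
to the input by default: all four chambers share one blood-pool
intensity, and at desk scale a small receptive field cannot distinguish
LV from RA without positional context. Optional per-channel instance
normalisation exists but is off by default: with patch-wise training its
per-patch statistics make the coordinate channels patch-relative, which
destroys exactly that positional signal.

3D training draws four foreground-centred 32³ patches per volume per
epoch (the heart occupies a few percent of the grid; uniform patches
would be nearly all background) and excludes a 4-voxel patch margin from
the loss so the zero-padded patch border — absent at full-volume
inference — teaches no wrong boundary context. 2D training uses up to 24
foreground slices per case. All stochastic choices are driven by the
config seed; sample order is fixed.

The learning-rate schedule (initial rate for the first 50% of epochs,
one tenth afterwards) defaults to the 2e-4 / 2e-5 clinical values with
6 / 480 default epochs (2D / 3D). Desk-scale overfit runs use a larger
initial rate (5e-3) with the same schedule shape: a single-volume
overfit takes a few hundred Adam updates rather than the tens of
thousands of the full regime, and the step size is chosen for that
budget. `TrainConfig.restarts` allows up to that many full training
attempts with derived seeds: an attempt is accepted as soon as its worst
per-class Dice on the training volumes clears 0.3, otherwise the best
attempt is kept. On such a short budget a tiny net occasionally settles
in a basin where two same-intensity classes merge and never separate;
the end-of-training health check detects exactly that, and the whole
procedure stays deterministic given the seed.

Oracle backends replace either net by reading the answer off the ground
truth: the 3D stage majority-downsamples a chamber-only reference
(vessels cleared — thin anomalous veins must stay in the blood pool for
the graph stage, even though the final labels merge them into RA/LA);
the 2D stage derives interior/boundary classes (boundary = blood-pool
voxel with a non-blood-pool 8-neighbour in its slice). Majority
downsampling breaks ties against background first, then toward the
lower code.

RoI cropping resamples to 64³, takes the bounding box of the coarse
foreground plus an 8-voxel margin (at 64³ scale), and maps it back to
full resolution; the RoI is a pure crop, so voxel + offset round-trips
exactly.

## Refinement

Chamber labels (upsampled nearest-neighbour) subtract from the blood
pool; the remainder is grown back by K=5 iterations of simultaneous
6-connected dilation restricted to the remaining pool. Competing labels
resolve by neighbour count, then lowest code — deterministic and
order-free. Bounded K keeps tube-like vessels out of the chambers;
whatever stays unclaimed is the vessel pool. K is exposed in the
pipeline config because phantom and clinical scales differ. The
myocardium mask is the upsampled Myo minus chamber-claimed voxels; no
high-resolution re-segmentation of Myo is attempted.

## Skeletons and candidate graphs

Smoothing: convolve the indicator with an all-ones 3×3×3 kernel and keep
voxels with neighbourhood sum ≥ 14 (majority of 27; idempotent on
half-spaces), applied k = 1..7 times. Note the operator is closing-like:
thick parallel contacts are stable, while thin high-curvature bridges
(radius ≲ 2 voxels) — the typical spurious connection from blood-pool
boundary errors — vanish after a few rounds, which is exactly what
separates abutting Ao/PA into distinct graph components at larger k.

Thinning uses the 3D surface-thinning skeletonizer of scikit-image
(topology-preserving, 26-connected). Graph extraction: skeleton voxels
with 26-neighbour count ≠ 2 are nodes; maximal degree-2 chains are
edges, resampled at 2 mm arc length along the chain (samples stay on
voxel centres so each sample's radius equals the distance-transform
value at its voxel exactly). Pure cycles anchor at their
lexicographically smallest voxel and become self-loop edges. The
distance map is computed once, on the unsmoothed vessel pool, because
the `r³` weight models true vessel calibre, which smoothing distorts.
Graphs identical in node/edge counts with node positions within one
voxel deduplicate to the smallest k.

## Graph matching

Each graph maps to a weighted point distribution: one bin per edge
sample, raw weight `r³` (the volume scale of blood pool around the
point), Euclidean ground distance. Frames are normalized — weighted
centroid to the origin, coordinates divided by the weighted RMS radius —
making the match invariant to position and global size; masses are
normalized to 1 because classical EMD with unequal masses is
ill-defined. EMD is solved as the transport linear program
(scipy/HiGHS); the test suite cross-checks it against an independent
integer-scaled min-cost-flow oracle.

Templates are built programmatically: each canonical (unjittered,
noise-free) anatomy variant is run through the very same vessel-pool
extraction and skeletonization as candidates, and its graph at smoothing
scale k=2 (or nearest available) becomes the template point set. Building
templates in the measurement representation matters: analytic centerline
templates sit systematically off the skeleton space (thinning trims tube
ends, chamber growth absorbs vessel roots) and mis-rank anatomies. Every
template sample doubles as a key point whose category (Ao / PA /
anomalous) is read off the nearest canonical centerline; a clinical-grade
library would replace this module with expert-curated graphs — the JSON
schema (`keypoints`, `connections`, `samples`, `anomalous_code`) is the
extension point.

Matching scores all (candidate scale, template) pairs and keeps the
minimum EMD; ties break toward the smaller smoothing scale, then the
lower template id. Whole candidate graphs — including multi-component
ones — are scored as single distributions; matching Ao/PA components
separately against sub-templates is a documented alternative we did not
take, as whole-graph mass layout already separates the tags on the
phantom suite. Edge categories come from majority vote of each sample's
nearest key point in the normalized frame; voxel labels from the nearest
edge sample within twice its inscribed radius; anomalous-category voxels
re-code to the template's `anomalous_code`. Remaining vessel-pool voxels
are absorbed by 26-connected competitive growth (same tie rules);
components with no labeled contact are reported unresolved rather than
guessed.

## Evaluation

Score tables have one row per case, columns LV…PA plus `overall` = mean
of the seven per-structure Dice values of that case (per-case structure
mean, not pooled voxels). `summarize` reports column means and sample
standard deviations (n−1; absent for n=1). The paired t-test uses
`t = mean(d)/(sd(d)/√n)` with n−1 df, two-sided; zero-variance pairings
raise an explicit error instead of returning ±∞. Fourfold
cross-validation in the CLI stratifies folds by anomaly flag so every
variant appears in every test fold.

## Problem sizes and determinism

Default sizes — 96³ phantoms, 20-case suite, 64³ training volumes, 32³
training patches — are the package's desk-scale study conditions; all
operations take explicit seeds and fixed orderings (lexicographic voxel
scans, lowest-id tie-breaks), so reruns are bit-identical.

## Known limitations

* The phantom suite's five templates cover the suite's five topologies;
  clinical CHD spans far more variants and would need a curated library.
* Oracle-backend results bound what the graph stages can do given
  *correct* upstream segmentation; trained desk-scale nets are weaker.
* The smoothing threshold (14/27) is exposed in config but untested
  against alternatives at clinical scale.
* No Hounsfield calibration, DICOM ingestion, mesh smoothing, or
  surface-distance metrics.

## Trained-backend RoI localisation

With oracle backends the RoI comes from the downsampled truth foreground.
With trained backends the coarse localisation is a fixed intensity rule
(downsampled intensity above half the blood-pool level): at desk scale
the contrast-filled blood pool is by far the brightest tissue, and
training a third, dedicated localisation net would add cost without
exercising any new machinery. A clinical deployment would replace this
rule with a coarse segmentation network.

Gradients are clipped to a global norm of 2.0 per step (measured typical
norms: median ~0.8, 99th percentile ~4), guarding against the rare
late-training blow-up of a small net at an aggressive step size.

Two implementation details matter for stable training. The coordinate
channels carry one sin/cos octave in addition to the linear coordinates:
a narrow net cannot carve sharp position-dependent boundaries from
linear coordinates alone. And the loss gradient splits at the softmax:
the Dice part flows through the softmax Jacobian, while the
cross-entropy part is applied analytically to the logits as
`(p - g)/(NC)` — routing it through clamped probabilities would zero the
restoring gradient exactly where a class has saturated toward zero,
turning an early class collapse into an inescapable basin.
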