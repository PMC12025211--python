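# Methods

## The problem

Body-composition analysis at the third lumbar vertebra (L3) — the areas
of skeletal muscle (SM), subcutaneous adipose tissue (SAT) and visceral
adipose tissue (VAT) on the L3 axial CT slice — is a prognostic biomarker
in oncology. Automating it means solving two learning tasks that are both
heavily class-imbalanced: the L3 slice is only ~5% of an abdomen–pelvis
series (slice-level imbalance in detection), and each tissue occupies a
minority of the pixels on the slice (pixel-level imbalance in
segmentation).

`ctbalance` implements an optimization-incorporated training strategy for
this setting. Two *correction design variables* (CDVs) are optimized
jointly with the ordinary training hyperparameters:

* the **augmentation ratio** `d_a`: the minority class is oversampled
  (rotations, horizontal/vertical flips of existing minority samples)
  until its count reaches `round(d_a × n_majority)`, with `d_a = 1`
  (exact 1:1 balance) as the upper bound of the search range and the raw
  class ratio as the lower bound. Detection only.
* the **class weights** `d_c`: per-class multipliers for a cost-sensitive
  weighted cross-entropy, `L = mean(−w_y log p_y)`, bounded below by
  `1/√f_k` for detection (class frequency `f_k`) and by the class pixel
  ratio `f_k` for segmentation.

The full design vector is `d = {d_h, d_a, d_c}`, where `d_h` are six
trainer hyperparameters with fixed search ranges: L2 regularization and
initial learning rate (log-scaled, `[1e-4, 1e-2]`), batch size
(`[10, 32]`), gradient-norm threshold (`[1, 6]`), epochs (`[5, 20]`) and
momentum (`[0.7, 0.99]`).

## Bayesian optimization

The objective is the inverse F1 score,
`1/F1 = (Precision + Recall) / (2 · Precision · Recall)`, minimized over
the design space. The segmentation objective macro-averages per-class F1
over the four foreground classes (SM, SAT, VAT, other) before inversion
(micro-averaging is available). `F1 = 0` is capped at `1e6` so the
surrogate stays finite.

Mixed variable types are encoded onto the unit cube: log-scaled axes pass
through `log` before affine scaling; integer axes are scaled continuously
and decoded by rounding to the nearest feasible integer. The surrogate is
a Gaussian process with a Matérn-5/2 kernel and per-dimension (ARD)
length-scales, hyperparameters set by marginal-likelihood maximization
with restarts, observation-noise floor `1e-8` (jitter escalates if the
covariance is singular). The acquisition is expected improvement in its
minimization form, `EI = (inc − μ)Φ(z) + σφ(z)`, `z = (inc − μ)/σ`,
maximized over 2048 uniform cube samples plus L-BFGS-B refinement from
the best few candidates. Initialization is a Latin-hypercube design of
`n_init = min(max(5, 2·dim), budget/2)` points; the `budget/2` clamp is
needed because at practical budgets (≈20) `2·dim` of the 9–11-dimensional
CDV spaces would leave almost no acquisition steps. Objective evaluations
that raise are logged and recorded at the cap, so a diverged training run
cannot abort the search.

Design selection never sees test data: the objective is evaluated on a
fixed inner train/validation split (80/20 by patient) of the training
folds, and the training seed is held fixed within one search so objective
differences are attributable to the design.

## Tasks, protocol, reference models

Cross-validation is patient-level and 5-fold: all slices of a patient
share one fold; fold sizes differ by at most one; leakage is asserted on
every run. Detection is binary slice classification; the predicted L3 for
a patient is the slice with the highest softmax P(L3) (ties → lowest
index), and the reported slice error is the signed offset to the nearest
L3-flagged slice. Segmentation trains on L3 slices only, with the dataset
augmented to 4× its size (originals retained), and codes
{0 background, 1 SM, 2 SAT, 3 VAT, 4 other}.

Trainer backends sit behind a seedable contract
(`fit(images, labels, design, weights, seed)` /
`predict_probabilities`). The shipped backends are deliberately small
CPU-scale reference models written in NumPy with hand-derived backprop
(verified against central finite differences in the test suite):

* detection — a residual CNN: 3×3 stem convolution, 2×2 max-pool, two
  residual blocks with identity shortcuts, global average pooling, linear
  head; input 16×16.
* segmentation — a three-level U-Net: 3×3 convolutions, max-pooling,
  nearest-neighbour upsampling, encoder–decoder skip connections, and a
  1×1 classifier head that also sees the raw input intensity directly
  (per-pixel intensity is highly class-informative, and the direct skip
  lets the few optimizer steps available concentrate on spatial
  disambiguation); input 24×24.

The optimizer is SGD with momentum, L2 weight decay on weight tensors,
and the *global* gradient norm clipped at the `gradient_threshold` design
variable before each update. Training inputs are standardized (global
mean/SD of the training set, stored on the model handle) — at the small
step budgets implied by the epoch range this is what makes the reference
models trainable at all. Every component of `d_h` verifiably changes
training (step counts, clipped norms and losses are recorded).

Full-scale backbones (deep residual classifiers, attention U-Nets,
transformer segmenters) plug in behind the same contract; the strategy
itself is backbone-agnostic.

## Preprocessing and post-processing

Preprocessing is window → stretch → resize: HU values are clipped
(saturated) to `[−190, 150]` — the soft-tissue window covering muscle and
fat; "adjusted to the range" is read as clipping because a rescale would
make the subsequent stretch redundant — then histogram-stretched so the
1st/99th percentiles (configurable) map to 0/1 with clipping, per slice;
constant slices map to zeros. Images are resized bilinearly, masks with
nearest-neighbour (the only choice that preserves categorical labels);
the native size is carried so physical areas can be recovered via the
squared resize ratio (a factor of exactly 4 for 512→256).

Post-processing vetoes implausible predictions with the original
(un-windowed) HU: a pixel predicted SM/SAT/VAT whose HU lies outside
[29, 150] / [−150, −50] / [−190, −30] respectively is reassigned to
"other". Reassignment between tissue classes would be ambiguous because
SAT's interval is a strict subset of VAT's, so the spatial prediction is
trusted for the class choice and HU only vetoes (a `nearest_valid` rule
is available behind a flag). The operation is idempotent and can only
shrink tissue classes.

A design note on the segmentation weight minima: the pixel-ratio rule
gives *larger* minima to majority classes — the opposite direction from
imbalance correction. It is implemented as specified, with
`min_rule="inverse_pixel_ratio"` available as a switch; the optimizer can
in any case raise minority weights above their minima.

## Evaluation

Per-class one-vs-rest confusion counts feed Jaccard `TP/(TP+FP+FN)`, Dice
`2TP/(2TP+FP+FN)` (the identity `D = 2J/(1+J)` is asserted), sensitivity
and specificity (`TN/(TN+FP)`, the standard form). Mean surface distance
uses boundaries defined as mask pixels with a 4-connected neighbour
outside the mask (image borders count as outside); directed mode averages
distances from the predicted boundary to the nearest true-boundary pixel,
symmetric mode averages both directions; output is in mm at the masks'
current resolution (native spacing × resize factor). Degenerate cases:
empty-vs-empty classes score 1 on overlap metrics, an empty boundary
makes MSD missing (NaN), never 0. Slice-level agreement uses Bland–Altman
limits `mean ± 1.96·SD` (n−1 denominator) with a strict-inequality
within-limits fraction (all-equal differences therefore give 0 — the
degenerate case is reported, not hidden). Tissue areas are
`pixels × spacing² × (native/current)²`; predicted-vs-reference agreement
uses ordinary least-squares R².

## The phantom generator

No public dataset exists for this task (clinical cohorts are private), so
the package ships a synthetic cohort generator that reproduces exactly
the statistical structure the strategy depends on — and nothing more:

* **imbalance**: `round(l3_fraction × slices)` contiguous L3 slices per
  patient (default fraction 0.05, ~40 slices per patient);
* **geometry**: an elliptical abdomen with an outer SAT ring, an SM band
  inside it, drifting VAT blobs in the interior, organ tissue ("other")
  elsewhere, and a posterior bone feature whose shape varies smoothly
  along z;
* **L3 signature**: on L3-flagged slices the bone grows wide transverse
  wings (with a raised-cosine decay over neighbouring slices), a
  deterministic geometric cue a small classifier can genuinely learn —
  the generator makes no claim to anatomy;
* **intensities**: per-tissue truncated normal draws whose supports are
  exactly the post-processing HU ranges; textural noise is folded into
  the truncated draw's SD (`√(tissue_sd² + noise_sd²)`), so tissue
  histograms lie wholly inside their declared ranges with no boundary
  spikes. HU are quantized to integers, as in real CT, which also makes
  the 16-bit-PNG round trip bit-exact (written with a +1024 offset
  recorded in the sidecar).

Default HU centres (SM 50, SAT −100, VAT −90, organs 35, bone 450,
background −1000; SDs 12–25, noise SD 5) are plausible CT values chosen
once; spacing defaults to 0.9 mm/pixel.

What the phantoms do **not** emulate: anatomical shape variation,
scanner/reconstruction artefacts, partial-volume mixing at tissue
interfaces, inter-patient intensity shifts, or any correlation structure
between slices beyond the smooth geometry. Passing tests on phantoms
therefore demonstrate that the optimization machinery, protocol and
metrics behave correctly and that the CDVs help under controlled
imbalance — not that clinical accuracy is achieved.

## Problem sizes and numerical choices

The packaged study conditions for the with/without-CDV comparison are 40
phantom patients of ~40 slices at 64×64 (pixel spacing 0.9 mm), 5-fold
patient-level splitting with one fold round evaluated per replicate,
optimization budget 20, three seeded replicates; network inputs are
16×16 (detection) and 24×24 (segmentation), mirroring the halving resize
of the original protocol at phantom scale. The "without CDVs" baseline
runs the same optimizer over `d_h` only, with `d_a` pinned at the raw
class ratio and `d_c` at the minima (a `baseline="none"` mode uses fixed
mid-range `d_h` instead). Float32 arithmetic in the reference nets;
max-pool backward splits gradient equally among tied maxima; argmax ties
everywhere resolve to the lowest index; all randomness flows from a
single master seed through tagged BLAKE2 sub-seeds (< 2³¹), making every
CSV byte-reproducible.

## Known limitations

* Reference models are far below clinical capacity; absolute phantom
  Dice/slice-error values are not comparable to published clinical
  numbers — only the with/without-CDV direction is meaningful here.
* Single-fold evaluation per replicate trades CV coverage for wall time;
  `folds=None` runs all five rounds.
* The GP treats integer axes by continuous relaxation with rounding;
  duplicate proposals after rounding are possible at small budgets.
* Histogram stretching is per slice by default, which discards
  inter-slice intensity relationships; pooled per-volume bounds are
  available (`volume_percentile_bounds`).
* DICOM/NIfTI ingest is minimal (single series, HU already calibrated or
  recoverable via slope/intercept).
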