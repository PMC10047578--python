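# Methods

This note records the models implemented in `cervitex`, the parameter
choices that matter, and the design decisions taken where the underlying
method family leaves room.

## Feature extraction

**Quantization.** Texture matrices are built on integer gray levels
`1..Ng` obtained by linearly rescaling each channel's own `[min, max]`
range.  Default `Ng = 8`: a standard texture-analysis alphabet that keeps
an 8×8 co-occurrence matrix and an 8-row run-length matrix well populated
even on small images.  A constant channel maps entirely to level 1 (the
range is degenerate, and level 1 is the only choice that keeps every
downstream statistic finite).  Quantization on per-channel min/max makes
all matrix features invariant to affine intensity changes per channel;
users wanting absolute-intensity sensitivity can quantize on a fixed range
themselves before calling the matrix builders.

**Run-length matrices.** Runs are maximal same-level segments along each
scan line of a direction; the four directions are horizontal,
anti-diagonal (up-right), vertical, and diagonal (down-right).  Each pixel
belongs to exactly one maximal run per direction, which yields the
conservation law `sum_ij j·P(i,j) = Np` enforced in the tests.  Features
use the canonical definitions: short-run emphasis divides by `j²`,
long-run emphasis multiplies by `j²`, low-gray-level weights divide by
`i²`.  Seven statistics per channel (SRE, LRE, GLN, RLN, RP, SRLGLE,
LRLGLE) are the default; the long-run high-gray-level emphasis is
implemented and exposed via `include_lrhgle` for users wanting the full
eight-statistic set.  Per-feature aggregation over directions is the
arithmetic mean — the usual rotation-robust choice, and the one that makes
the feature vector exactly invariant under horizontal mirroring (mirroring
permutes the 45°/135° scans and fixes 0°/90°).

**Co-occurrence matrices.** Offset distance `d = 1` (the universal
default); matrices are symmetrized by adding the transpose before
normalization, which equalizes the two marginals (`mu_x = mu_y`) as
Haralick's marginal-based statistics assume, and gives the same mirror
invariance as above.  The 22-statistic set is the standard
Haralick + Soh + Clausi aggregation (autocorrelation, contrast, two
algebraically equivalent correlation forms, cluster prominence/shade,
dissimilarity, energy, entropy, two homogeneity forms, maximum
probability, sum-of-squares variance, sum average/variance/entropy,
difference variance/entropy, the two information measures of correlation,
and the normalized inverse-difference pair).  Numerical conventions:
natural logarithms with `0·log 0 := 0`; when a marginal standard deviation
is zero (constant channel) the correlations and information measures are
defined as 0, keeping outputs finite and deterministic on degenerate
inputs.  Sum variance is centred on the sum average; Haralick's original
formula centres it on the sum entropy, which is widely regarded as a
misprint, and we do not reproduce it.

**HOG.** One descriptor per image, computed on the luma (ITU-R BT.601)
grayscale, not per channel — gradient structure is essentially shared
across channels, and the single-window geometry keeps the raw dimension
fixed.  The window pipeline is: centred crop to 200 rows × 100 columns
(the cervix is centred in standard colposcopy framing; images smaller than
the crop are bilinearly upscaled first so the output shape is total),
bilinear resize to 128 rows × 64 columns, values in [0, 1].  Sizes quoted
width-first in the detection literature ("64 × 128") are therefore arrays
of shape (128, 64) here; the convention is recorded in the config and does
not affect any downstream width.  Gradients are central differences
(one-sided at borders); orientation is the two-argument arctangent folded
to [0°, 180°).  9 unsigned bins, 8×8-pixel cells, magnitude-weighted votes
linearly interpolated between the two nearest bin centres (circular over
180°), 2×2-cell blocks at stride one cell, L2-Hys normalization with clip
0.2.  Raw length is (16−1)(8−1)·4·9 = 3780.

**PCA.** The raw descriptor is reduced to 20 components.  Components are
computed by full SVD and made deterministic by fixing each component's
largest-magnitude loading to be positive.  By default the PCA is refitted
on every cross-validation training split so no test-set information leaks
into the projection; `paper_mode=True` fits it once on the whole dataset,
matching the single-pass protocol of feature-table workflows built around
standalone ML tools (and the CLI `extract` command necessarily uses the
dataset-level fit, since it materializes a table before folds exist).  On
the synthetic data the two protocols give indistinguishable accuracy; the
fold-wise default is the statistically defensible one.

**Fusion.** Plain concatenation GLRLM (21) ‖ GLCM (66) ‖ HOG (20) = 107,
in the order the block sizes are conventionally enumerated.  No scaling is
applied at fusion time; the logistic classifier standardizes internally on
its training folds, and tree/table/Bayes models are scale-free or
discretized.

## Classifiers

The six benchmark classifiers mirror the semantics of the classic Weka
schemes of the same names:

- `naive_bayes`: Gaussian class-conditional naive Bayes.
- `bayes_net`: tree-augmented naive Bayes.  Features are discretized with
  Fayyad–Irani recursive MDL entropy binning (features where no cut passes
  the MDL criterion collapse to one bin and drop out); a maximum spanning
  tree over conditional mutual information given the class (Prim's
  algorithm, ties toward lower feature indices) augments the naive
  structure; conditional probability tables are Laplace-smoothed (α = 1).
- `random_tree`: one unpruned decision tree drawing √p random feature
  candidates per split.
- `random_forest`: 100 such trees with majority soft-voting.
- `decision_table`: features MDL-discretized as above; greedy forward
  selection adds the feature that most improves leave-one-out table
  accuracy (exact LOO, majority fallback for empty cells, global-majority
  tie-break) and stops when no strict improvement remains; prediction
  returns the matched cell's training class frequencies, falling back to
  the global distribution for unseen cells.
- `logistic`: L2-penalized logistic regression (C = 1) on features
  standardized within the training fold.

All six expose class probabilities and are deterministic given a seed.

## Evaluation

Stratified k-fold cross-validation (default k = 10, shuffled with a fixed
seed); per-fold class proportions are within one instance of the global
proportions, and a class with fewer than k instances is a hard error.  The
abnormal class is positive.  Metrics from pooled confusion counts:
accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
precision = TP/(TP+FP), recall (identical to sensitivity by definition —
both are reported because results tables conventionally print both), and
F1 = 2PR/(P+R).  The mean absolute error is the probability-calibration
form: the mean over instances and both classes of |predicted class
probability − one-hot truth|, so a perfect hard classifier scores 0 and a
maximally uncertain one scores 0.5.  Metrics with a zero denominator (e.g.
precision when nothing is predicted positive) are reported as 0 and
flagged in `MetricsReport.degenerate` rather than raised, so benchmark
grids stay total.

## Synthetic data

No labeled cervigram compilation is publicly deposited, so the test bed is
generated.  Each image is a sum of (i) a Gaussian-smoothed white-noise
field with standard deviation `correlation_length` pixels, normalized to a
fixed amplitude of 25 gray levels — this sets run-length and
co-occurrence granularity; (ii) an oriented sinusoidal grating of
wavelength 16 px with amplitude `contrast_scale` and orientation
`orientation_deg`, random phase per image — this sets co-occurrence
contrast and the dominant edge orientation HOG measures; (iii) per-channel
offsets `base_intensity` plus sensor noise of 2 gray levels.  The default
class pair separates all three knobs (correlation length 1 vs 8 px,
contrast 5 vs 40, orientation 0° vs 90°), so each feature family alone can
separate the classes and the fusion-is-competitive property is genuinely
testable; setting both classes to the same spec gives an exact null.
Default image size 256 × 128 so the HOG crop/resize path is exercised
non-trivially.  What the generator does **not** emulate: specular
reflections, vignetting, anatomical structure, instrument color casts, or
inter-patient variability — passing tests demonstrate that the pipeline
measures the texture statistics it claims to measure and recovers classes
that differ in them, not that those statistics suffice on clinical images.

## Augmentation

Each augmented copy applies rotation uniform in ±15°, shear uniform in
±0.2, translations uniform within ±0.2 of each image dimension, and
independent fair-coin horizontal/vertical flips, with out-of-frame pixels
filled with constant 0 (all interpreted as maxima of uniform draws, the
convention of the mainstream augmentation frameworks).  The per-image
expansion count is explicit configuration — published dataset totals do
not determine it, since original image counts are not public.  Output is a
pure function of (dataset, config, seed).

## Problem sizes and determinism

The shipped test suite runs the end-to-end recovery checks at 100 images
per class (separated and null conditions) and the full seeded CLI
determinism check at 12 originals per class with one augmented copy each —
sizes at which every statistical assertion is already far from its
threshold while the whole suite completes in about a minute.  All
randomness flows from explicit integer seeds (`numpy.random.default_rng`,
scikit-learn `random_state`), and rerunning any pipeline with the same
inputs and seed reproduces results byte-for-byte.

## Known limitations

- Quantization on per-channel min/max means a single outlier pixel can
  compress the effective dynamic range of the level alphabet.
- The decision table's exact LOO selection is O(rounds × p × n) and
  becomes slow beyond a few thousand instances.
- The MDL discretizer is univariate; class structure visible only in
  feature interactions is invisible to `bayes_net` and `decision_table`.
- The HOG raw dimension depends only on the fixed window geometry; images
  with aspect ratios far from the crop lose peripheral content to the
  centred crop.
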