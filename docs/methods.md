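# Methods

## Problem setting

Small brain-MR classification datasets (hundreds to a few thousand slices)
rarely support end-to-end deep training. The pipeline implemented here
treats fixed (frozen, pretrained) convolutional networks purely as feature
extractors, asks a bank of classical classifiers which representations carry
signal, and fuses the best few representations by concatenation before the
final classifier. The package implements the full pipeline with
deterministic toy extractors and synthetic data; real backbone extractors
register through the same `ExtractorSpec` interface (`register_extractor`)
but are deliberately not bundled — nothing in the library, tests, or
acceptance run needs downloaded weights.

## Preprocessing

Extreme-point cropping removes the dark background around the head:

1. threshold after Gaussian smoothing — defaults: threshold 45 on the 0–255
   scale, smoothing sigma 2 px. The cropping recipe this follows is usually
   quoted without parameter values; fixed defaults keep runs reproducible
   and both are configurable;
2. binary erosion then dilation, 3×3 structuring element, 2 iterations each
   (an opening; leaves solid convex components untouched, removes speckle);
3. largest 8-connected foreground component; its boundary pixels are the
   contour, returned in lexicographic (row, col) order for determinism;
4. extreme points: min/max column and min/max row over the contour, ties
   broken by lowest row then lowest column;
5. crop to the spanned box, inclusive at both ends, margin 0 by default,
   clipped at image borders.

Coordinates are 0-based (row, col). Resizing uses bicubic interpolation
(scikit-image, order 3, no anti-aliasing) so a constant image maps exactly
to the same constant. Dihedral augmentation provides both an exhaustive mode
(the 8 group elements in fixed order — rotations k = 0..3, unflipped then
flipped) and a seeded random mode (one draw of rotation count and flip);
augmentation is intended for the training split only, after splitting, to
avoid leakage. Splits take `floor(train_fraction * n)` training samples
(0.8 × 253 → 202/51; 0.8 × 3000 → 2400/600); stratified mode distributes
per-class floors first and assigns the remainder by largest fractional
part.

## The classifier bank

Nine classifiers behind one train/predict/score interface. Standard members
are delegated to scikit-learn; two are implemented in-package:

| member | implementation | hyperparameters |
| --- | --- | --- |
| `fc` | in-package numpy | single linear layer + softmax, cross-entropy, Adam, lr 0.001, 100 epochs, zero init |
| `gaussian_nb` | sklearn | variance smoothing 1e-9 |
| `adaboost` | sklearn | 150 estimators, depth-1 trees (depth configurable) |
| `knn` | sklearn search + in-package vote | k grid {1,2,3,4}, Euclidean |
| `rf` | sklearn | tree grid 1..150 (full) or {10,25,…,150} (reduced), √d features/split |
| `svm_linear/sigmoid/rbf` | sklearn SVC | γ ∈ {1e-5,1e-4,1e-3,1e-2}, C ∈ {0.1,…,1e4}, coef0 = 0 |
| `elm` | in-package | hidden grid {5000..10000} (full) or {50,100,200} (reduced), sigmoid |

Notes and choices:

* **FC head.** Zero weight initialization makes the untrained head emit the
  uniform distribution (per-sample loss ln M) and training deterministic
  without a seed. An optional `track_best_epoch` mode records the best
  per-epoch evaluation accuracy instead of the final epoch; final-epoch
  reporting is the default.
* **k-NN vote ties.** Even k can produce tied votes; the tie goes to the
  label of the nearest neighbor among the tied classes. This rule cannot be
  expressed through sklearn's `predict` (which breaks ties by class order),
  so the vote is implemented on top of sklearn's neighbor search.
* **SVM kernels.** C is the soft-margin penalty only; the sigmoid/rbf kernel
  offset c₀ is 0 (treating the same symbol as both a margin penalty and a
  kernel constant would double-use it). Multi-class is one-vs-one (libsvm's
  native scheme). The SMO solver is capped at 200 000 iterations per fit
  (configurable): large-C grid points on non-separable data otherwise
  iterate quasi-indefinitely, and a capped fit is still a usable (slightly
  early-stopped) solution that grid search rarely prefers.
* **ELM.** Hidden weights/biases are uniform(−1, 1) from a seeded generator;
  `β = pinv(H) T` with one-hot targets, prediction by argmax with ties to
  the lowest class index. The sigmoid activation is the canonical choice
  (tanh and relu selectable). Tests cross-check the pseudoinverse solve
  against an explicit SVD least-squares solve (agreement ≤ 1e-8) and verify
  the normal-equation residual ‖Hᵀ(Hβ−T)‖∞ ≤ 1e-6 plus exact interpolation
  when H is square and full-rank. The full 5000–10000 hidden grid is
  impractical for a test suite; the reduced grid {50, 100, 200} is used in
  desk-scale runs and both are configurable.
* **Random forest.** Bagging means a single tree sees only its bootstrap
  sample, so a one-tree forest memorizes in-bag points only; tests assert
  exactly that plus whole-set memorization by a 50-tree forest.
* **AdaBoost.** With depth-1 stumps the XOR pattern is not boostable (every
  stump has weighted error 1/2); the XOR test uses depth-2 base trees via
  the configurable depth.

**Grid-search protocols.** `paper_faithful` scores every grid point on the
provided evaluation set — when that set is the test set, this reproduces the
original study protocol and is a documented leakage; it is kept as an
explicit, flagged mode. `holdout` (the default) carves a seeded stratified
80/20 validation split out of the training data, selects there, refits on
the full training set, and only then touches the test set. Ties between
grid points go to the earlier point in grid order.

## Selection rule

Rank extractors by the mean of their nine accuracies. The ranking key is
`(-round(mean, 4), population_std, extractor_id)`: rounding to the 4-decimal
display precision is order-preserving for distinct means, and makes means
that agree at display precision (the only kind of tie a published grid can
show) compare equal so the lower population standard deviation decides;
exact float ties behave identically. The final fallback is lexicographic,
for determinism. Walking down the ranking, an extractor whose family is
already selected is excluded with reason `homogeneous-family` — same-lineage
architectures yield largely redundant feature spaces, and concatenating them
wastes the ensemble slot. Every exclusion and tie-break is kept in the
`SelectionResult` audit fields.

Population (divide-by-n) standard deviation is used; the one benchmark tie
this must break resolves identically under either convention. The greedy
walk over a partition-matroid constraint (≤ 1 per family) is optimal, and
`brute_force_select` — the exhaustive family-distinct subset optimum under
the same key — is kept as an independent test oracle.

The three published 13×9 benchmark grids are bundled
(`featfuse.benchmarks`) as selection inputs. Their printed "Average"
columns were computed before rounding, so re-aggregating the printed
4-decimal cells can differ by one unit in the last digit; the frozen
expectations cover only the rounding-consistent aggregates (two row means,
two column means), while the top-3 selections are reproduced on all three
grids, including the display-mean tie on the 2-class grid (two rows whose
printed cells sum identically) and the family exclusion on the 4-class grid.

## Ensembling

Concatenation order is selection-rank order (column order is irrelevant to
every bank member but fixed for reproducibility). No cross-member rescaling
is applied by default; an optional per-member z-scoring exists for SVM/ELM
sensitivity studies (`concatenate_features(..., standardize_members=True)`,
`featfuse.features.zscore_table`). Hyperparameter grids are re-searched for
every ensemble row rather than reusing per-extractor winners — the combined
feature space is a different problem. Enumeration for
k selected members emits all non-empty combinations in size order: 7 rows
for k = 3.

## Synthetic data

**Phantoms** emulate the geometry the crop stage assumes: dark background
(10), bright elliptical "brain" (120, semi-axes ~24–42 px in a 128×128
frame, jittered center), optional hyperintense blob (+80) for tumor classes,
Gaussian noise (sd 4 by default), and a guaranteed-dark border (16 px). The
4-class blob regimes (large off-center / rim-hugging / small central) are an
artifact convention for generating four separable classes, not radiology.
What phantom tests show: the geometric pipeline (threshold–clean–trace–crop–
resize–extract–classify) is correct and the stages compose; what they do not
show: robustness to real MR intensity distributions, bias fields, Rician
noise, or anatomy.

**Feature banks** draw class-conditional Gaussians: each extractor has
informative axes on which the means of its *separated* classes sit
`class_separation` apart along per-class orthonormal directions (QR of a
seeded draw when the informative subspace is wide enough), all other axes
are isotropic noise. Extractors in the same family share the per-class
directions (drawn from a family-keyed stream), so family mates' class means
are collinear — the redundancy premise of the selection rule, measurable as
correlation ≈ 1. Isotropic Gaussian noise keeps every bank member well-posed
and makes Bayes accuracy computable for test design. The complementary bank
used in the end-to-end checks has four classes and five extractors: two
informative on disjoint class pairs (separation 6 sd — each alone tops out
near 0.75 accuracy), one family mate of the first (separation 5 sd), and two
pure-noise extractors; n = 400 samples, 12 dimensions per extractor. Which
of the two family mates outranks the other at a given seed is sampling
noise; the invariant property is that exactly one is excluded by the family
rule.

## Numerical choices

* Seeds: one master seed feeds named substreams (`split`, `bank`,
  `classifiers`, `phantom`, …) via CRC32-keyed `SeedSequence` mixing, all
  below 2³¹, so stages re-run independently and reproducibly.
* Accuracy display rounding is 4 decimals (matching published grids); all
  internal comparisons use full precision except the documented
  display-precision tie check.
* `morph_clean` guards scipy's `iterations=0` convention (which would mean
  "until convergence") — zero iterations is the identity.
* CSV feature tables round-trip exactly (`%.17g` on write, round-trip float
  parsing on read); HDF5 is provided for large dimensions.

## Problem sizes

Desk-scale defaults keep a full experiment (5 extractors + 7 ensembles × 9
classifiers, all grids) around half a minute: n = 400 samples, d = 12 per
extractor, reduced RF/ELM grids. The phantom run uses 200 images at
128×128. These sizes are the package's test conditions; the pipeline itself
is size-agnostic.

## Known limitations

* No bundled pretrained backbones; the 13-backbone study design is exercised
  through the bundled published grids and synthetic banks.
* 2-D slices only — no volumes, skull-stripping, bias-field correction, or
  registration.
* `paper_faithful` grid search is intentionally leaky (documented historical
  protocol); use `holdout` for honest estimates.
* Phantoms and Gaussian banks validate mechanics, not clinical performance.
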