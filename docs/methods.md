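# Methods

This note documents the models, procedures and design choices behind
`ribfrac`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## Problem setting

The pipeline targets 2-D "unfolded rib cage" images: planar reformations of
volumetric CT in which every rib appears as a bright, roughly horizontal
band on a dark background. Fractures are point-annotated (x, y, terminal
class) and belong to one of four renderable types: nondisplaced, ad latus
(sideways offset of the fragments), ad longitudinem cum contractione
(longitudinal compression with fragment overlap) and ad longitudinem cum
distractione (longitudinal gap). The angulated "ad axim" type is out of
scope. Detection and typing are phrased as 5-class patch classification
(the four fracture types plus "no fracture") followed by lesion-level
aggregation.

## Synthetic unfolded-rib generator

Real unfolded-rib data is privacy-restricted, so the generator is a
first-class module, not a test stub. It renders:

* horizontal rib bands (default 8 bands, 9 px thick, intensity 180 on
  background 20) with slight seeded sinusoidal curvature (amplitude
  ≤ 2.5 px), evenly spaced with margins that keep every motif inside the
  image;
* fracture motifs cut into the bands, at most one per band so ground truth
  is never ambiguous: a 2-px dark transverse line (nondisplaced), a
  vertical offset of the distal band half by `motif_magnitude` px
  (ad latus), a brighter overlap zone of `motif_magnitude` columns where
  the fragment intensities add (cum contractione), and a background-level
  gap of `motif_magnitude` columns (cum distractione);
* additive Gaussian pixel noise (σ default 4 grayscale units), clipped to
  8-bit.

Everything derives from `(seed, image_id)` through three independent
substreams (band layout, noise, fracture placement), so the fracture-free
rendering of an image is pixel-identical outside the motifs — which is also
how the test suite verifies that every annotation's extent box actually
changed pixels.

The separability of the four motifs is monotone in `motif_magnitude` and
inversely monotone in `noise_sigma`; the geometric signatures (band-center
offset equal to the magnitude, gap run length, overlap-zone brightness) are
asserted directly on rendered segments.

What the generator does **not** emulate: true CT texture and partial-volume
blur, rib-unfolding distortion artifacts, anatomical variation (costal
cartilage, old healed fractures), subacute/chronic fracture appearance, and
annotation jitter. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the classifier can recover well-separated
classes; they say nothing about performance on clinical PMCT data.

## Preprocessing

Images are cropped to a configured window (default 500 rows × 1000
columns; the generator already emits this geometry, so the default crop is
an identity) and enlarged to 300 %. Pixel-area-relation resampling with an
integer factor is exact block replication — every output pixel's footprint
lies inside one source pixel — which preserves constant regions and means
exactly. Annotations are kept in the cropped frame and mapped to the large
frame by block-center mapping `X = 3x + 1`, so a fracture center stays
centered in its 3×3 block; the transform is exactly invertible.

Coordinate convention, fixed package-wide: 0-based, x = column (left to
right), y = row (top to bottom).

## Patch mining

* Positives: one 99×99 patch on the annotated center plus 16 augmented
  patches (10-px steps, 4 per direction along both axes). Since the
  largest shift (40 px) is smaller than the half-window (49 px), the
  annotated center remains inside every augmented patch. Patches whose
  window crosses the border are dropped; a fracture whose *original*
  window is out of bounds is skipped with a warning.
* Curation: manual removal of information-losing augmented samples is not
  reproducible, so it is replaced by a pluggable predicate; the default
  keeps a shifted sample iff the annotation's extent box overlaps the
  window by ≥ 0.5 of the box area.
* Negatives: sliding 99×99 windows at 25-px stride over fracture-free
  images, grid anchored at (0, 0), fully-inside windows only — 57 × 117 =
  6,669 windows on the default 1500×3000 frame. A seeded uniform subset
  balances the negative count to the positive one.
* Grouping: all representations of one fracture share a group id; every
  negative window is its own group (aggregation unit).

## Partitioning

Splits operate on whole groups, stratified by terminal class: within each
class, groups are shuffled and moved to the test side while that brings the
class's test sample count closer to the target fraction; every class keeps
at least one group on each side, and a class with a single group raises an
error rather than silently degrading. The k-fold partition deals each
class's shuffled groups round-robin, so per-class group counts per fold
differ by at most one. Both hand-rolled procedures exist because the exact
stratification guarantees they provide are asserted by the test suite;
leakage (a group id crossing any train/validation/test boundary) is checked
explicitly on every produced split.

The realized 70/30 split is measured on sample counts (groups vary in size,
so partitions vary slightly); the default tolerance is ±0.03 and can be
disabled for deliberately tiny fixtures.

## Classifier

The head is fixed: dense(198) → ReLU → dense(198) → ReLU → dropout(0.5) →
dense(n_classes), on top of a convolutional backbone. Two backbones ship:

* `small_convnet` (default): 3×3 average-pool downsample of the 99×99
  patch, two valid 3×3 conv + max-pool stages (8 and 16 channels), 576
  features. It trains in seconds per epoch on one CPU and is the backbone
  used by the test suite and the study.
* `residual`: a deeper randomly-initialized backbone with two
  identity-shortcut residual blocks and a wider final stage.

All layers (convolution via im2col, pooling, dense, inverted dropout,
residual blocks), Adam, and the softmax cross-entropy loss are implemented
in NumPy inside the package; backward passes are exact gradients of the
forward computation and are verified against finite differences in the
tests. Patches enter natively at 99×99, single channel, scaled to [0, 1].

Training runs in two phases: phase 1 freezes the backbone and fits the
head with Adam at lr 1e-4; phase 2 unfreezes everything and fine-tunes at
lr 8e-5 (both capped at 100 epochs by default). In each phase the
validation loss drives early stopping (patience 15) with restoration of the
best-validation-loss weights, and a plateau rule multiplies the learning
rate by 0.1 (configurable) after 2 stagnant epochs. While the backbone is
frozen its features are computed once per phase — an exact optimization,
since frozen features are constants. Validation macro-F1 over the terminal
classes is recorded per epoch; across CV folds, the configuration with the
highest mean best-epoch validation F1 wins, ties broken by fewer epochs to
best, then candidate order.

Numerical determinism: initialization, batch order and dropout masks all
derive from one seed; identical seeds give bit-identical histories on CPU.

## Aggregation

Presence gate over the predicted labels of a group's representations:
`Y = 0` iff the label sum is 0 (every representation voted "no fracture"),
else `Y = 1` — a single fracture vote suffices, maximizing lesion-level
sensitivity by construction. When `Y = 1` the type is the fracture class
with the largest mean pre-softmax score over the representations; class 0
is excluded from that maximization (returning it would contradict the
gate), and all argmax ties in the package break toward the lowest class
index for determinism. Aggregation is permutation-invariant in the
representations and is cross-checked against a literal loop-written
enumeration of both rules on random groups.

The mean is taken over all representations that survived mining/curation
for the group — curated-out patches never reach the aggregator.

## Evaluation

Three taxonomy levels restrict to items whose *true* label is in scope
(high: all; mid: true fractures; low: true displaced) and map terminal
labels to level classes. Predictions outside the level's classes (e.g. a
true displaced fracture predicted "no fracture" at mid level) occupy an
explicit `out_of_level` confusion column: they count against the true
class's recall but against no in-level precision. Dropping them would
silently inflate scores. Mid- and low-level scores are macro-averaged
(classes weighted equally regardless of support) because those tasks are
imbalanced; zero-support classes contribute 0 and are flagged in the
report. Relative confusion matrices are row-normalized, so the diagonal
equals per-class recall — an identity asserted in the tests. The
"standard" assessment scores every patch; the "aggregated" assessment
scores one item per group.

A note on comparing the two assessments: aggregation can only help a
fracture group that holds at least one correct vote (the gate then makes
the whole group correct), but overall accuracy re-weights items — a single
misclassified negative counts 1/n_groups aggregated versus 1/n_patches
standard — so the aggregated accuracy is guaranteed to dominate the
standard one only on group sets in which each group holds at least one
correctly-labeled patch. The end-to-end check verifies exactly that
conditional dominance, plus that no fracture group with a fracture vote is
ever aggregated to "no fracture".

## End-to-end study conditions

The parameter-recovery study (`ribfrac.experiment.run_study`) uses the
separable regime: motif magnitude 14 px, noise σ 2, four fractures on eight
bands per image, 15 positive and 6 negative images (≈ 1,750–2,050 patches
after curation and balancing), a 70/30 grouped split with a 15 % validation
carve-out, the `small_convnet` backbone, and the two-phase schedule with a
30-epoch cap per phase — sizes chosen so the full study runs in about half
a minute per seed on one CPU while leaving the schedule's patience rules
fully active. Seeds 0–2 are exercised by the test suite.

## Known limitations

* The backbone is randomly initialized; no large-scale pretraining is
  involved, so phase 1 amounts to fitting the head against fixed random
  convolutional features rather than against transferred natural-image
  features.
* The synthetic regime is far easier than clinical data; reported study
  metrics are ceiling values demonstrating machinery correctness, not
  clinical performance estimates.
* Negative mining assumes annotation completeness of positive images is
  irrelevant (negatives come only from fracture-free images); partially
  annotated positive images would require exclusion-zone mining.
* Metric uncertainty (bootstrap CIs) is not computed.
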