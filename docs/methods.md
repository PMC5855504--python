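# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the desk-scale results do and do not show.

## Segmentation/classification model (Lesion Indexing Network)

The segmenter is a fully-convolutional residual encoder–decoder producing
one score map per class at input resolution, with 4 classes: background
plus the three lesion categories (melanoma, seborrheic keratosis, nevus).
A single network therefore yields both the segmentation (non-background
argmax) and coarse per-class classification maps; this 4-way per-pixel head
is the minimal design that serves both tasks at once.

Residual blocks come in three flavors, all **pre-activation**
(BN → ReLU → conv, with the addition last and no post-add rectifier):

* *plain*: two 3×3 convolutions;
* *bottleneck*: 1×1 reduce (C→C/2), 3×3, 1×1 restore;
* *Residual-in-Residual (RiR)*: an outer identity shortcut wrapping two
  bottleneck residual units plus a 3×3 transition convolution.

Pre-activation ordering was chosen so that a block with all-zero weights is
exactly the identity map (the branch ends in a convolution), which makes
the identity-shortcut property directly testable and eases gradient flow.
The RiR branch ends in a transition convolution for the same reason.

Depth presets: `tiny` (2 stride-2 stages, 1 block per stage, base width 8,
10 weighted layers, minimum input 16) is the preset every training test
uses; `full` (3 stride-2 stages, 4 RiR blocks per stage, base width 32,
~92 weighted layers, minimum input 64) reproduces the deep
architecture family structurally and is exercised only for construction
and parameter-count contracts — CPU training of the full preset is out of
scope. Inputs are edge-padded to a multiple of the total stride and score
maps cropped back, so any input ≥ the minimum side is accepted and output
spatial shape always equals input shape. Decoder upsampling is
nearest-neighbour ×2 followed by a learned 3×3 convolution per stage.

Two networks are trained on complementary augmentations — the
rotation-balanced dataset DR and its element-wise randomly mirrored pair
DM — because mirrored near-duplicates inside one training set encourage
overfitting; keeping them in separate networks and summing their test-time
score maps (over all model × scale pairs, bilinearly interpolated back to
the input resolution) is the fusion rule. Summation order is irrelevant;
the segmentation mask and the final renormalized index are invariant to
positive rescaling of the fused maps.

## Augmentation

Rotation balancing: each class is rotated at a class-specific step — the 0°
copy counts as one of the 360/step copies, so a class of n images yields
exactly n·360/step (this is the only reading consistent with the published
counts 374→7480 at 18° and 1372→10,976 at 45°). Right-angle rotations are
exact index permutations; oblique rotations keep the image size and fill
exposed corners by reflection, avoiding black-corner artifacts that would
leak class information. Patch balancing: over-represented classes are
down-sampled uniformly without replacement to a cap; under-represented
classes gain 90/180/270° rotated copies (count × 4 with all three angles).

## Lesion Index Calculation Unit

Coarse maps are normalized per pixel by subtracting the per-pixel minimum
and dividing by the sum of the shifted values; a pixel where all three maps
agree falls back to the uniform 1/3. The distance map assigns each lesion
pixel its Euclidean distance to the nearest non-lesion pixel, with the
image edge counting as border (implemented as an exact Euclidean distance
transform on a zero-padded mask), then divides by the maximum so the
deepest interior pixel has weight 1. Max-normalization is cosmetic — the
final index is renormalized to sum to 1, so any positive rescaling of the
distance map cancels — but fixes a reproducible scale for inspection. The
index is the distance-weighted mean of each normalized map over the lesion
area; an empty lesion yields the uniform index with an explicit flag, and
argmax ties resolve to the lowest class id.

## Patch classifier (Lesion Feature Network)

Fixed topology: 12 trunk convolutions in 4 stages of (3×3, 1×1, 3×3) —
the 1×1 convolutions integrate features between the 3×3s — with batch
normalization between every convolution and its rectifier, 2×2 max pooling
after stages 1–3, global average pooling after stage 4, one fully connected
layer to 5 classes. Width presets per stage: standard (16, 32, 64, 128),
narrow (16, 16, 16, 32), wide (32, 64, 64, 128). Pooling placement (max
pooling between stages, average pooling at the end) is the natural reading
of a design that uses both kinds once.

Training: SGD with momentum 0.9, initial learning rate 0.01, step decay
×0.1 (every 5 epochs by default; the decay factor is fixed, the step length
configurable since only the factor is canonical), mini-batches, 80/20
train/validation split by seeded shuffle. The class-weighted softmax loss
multiplies each sample's cross-entropy term by the weight of its true class
— weights (1, 1, 5, 3, 8) for (B, PN, NN, MC, S) — making the loss linear
in the weight vector and exactly equal to the plain loss at unit weights.
Weighting the per-sample loss term (rather than the logits) is the standard
reading of class-weighted cross-entropy.

## Numerical engine

The networks run on a small numpy engine (`dermlin.nn`) with explicit
forward/backward passes: im2col convolution, batch normalization with
running statistics, 2×2 max pooling, nearest-neighbour upsampling, global
average pooling, linear layers and identity-shortcut wrappers, optimized by
SGD with classical momentum. All arithmetic is float64; gradients were
verified against central finite differences to ~1e-10. Given a seed and
single-threaded BLAS, training histories are bit-for-bit reproducible.
Softmax losses use max-subtraction stabilization throughout.

## Synthetic study conditions

The generator produces what the pipeline assumes, not clinical realism:

* **Lesion images** (default 96×96): skin-toned background with low-
  frequency mottling; one star-shaped blob lesion per image (radial
  harmonics keep the region star-convex, hence a single connected
  component, matching the one-lesion-per-image convention); dark hair
  strokes (quadratic Bézier curves, ~3 per image at the default density)
  and ruler scale-marks as structured noise. Class signatures are
  documented synthetic proxies: melanoma = very dark + strong speckle +
  irregular border; seborrheic keratosis = mid brown + coarse bumpy
  texture; nevus = smooth reddish-brown + regular border. The `contrast`
  parameter (default 0.6) blends lesion color toward skin; at contrast 1
  with no noise a plain Otsu threshold recovers the mask (JA > 0.95),
  anchoring the generator against a classical oracle.
* **Feature annotations**: superpixels on a regular grid, each labelled by
  a seeded draw whose default frequencies are proportional to the original
  (pre-balancing) patch imbalance — background ≫ pigment network ≫
  milia-like cysts > negative network > streaks ≈ (90 : 80 : 5 : 3 : 2) —
  and non-background superpixels get their class texture stamped exactly
  (reticular dark grid, inverted light-on-dark grid, bright dots on a
  darkened field, parallel dark streaks), so label files match the pixels
  by construction.
* **Coarse-map stacks** for index refinement: per-pixel Gaussian noise
  (SD 0.35) on all three maps; the true class raised by the interior margin
  (default 0.3) on pixels with normalized border distance ≥ the band width
  (default 0.2); a random decoy class raised by (7/3)× the interior margin
  on the border band. This emulates the regime motivating distance
  weighting — the skin-like border produces a strong wrong-class response —
  and the noise scale is set so the border band genuinely pulls a plain
  unweighted average toward the decoy while the distance-weighted index
  still recovers the true class. With zero margins both readers fall to
  chance.

Because lesions are colorimetrically separable blobs, passing desk-scale
tests shows the machinery (augmentation, training, fusion, refinement,
scoring) is correct — it does not show clinical-grade performance on real
dermoscopy, where published scores require the full external dataset and
GPU-scale training of the deep preset.

## Desk-scale problem sizes

Chosen once as the package's reference conditions: segmentation training on
120 synthetic lesions (40 per class, 96×96, seed 0), center-crop factor 0.8
then resize to 64×64, tiny preset, SGD lr 0.01 / momentum 0.9 / batch 8,
10 epochs; evaluation on 30 held-out images (seed 1) with two networks ×
two scales (64, 96) and mean per-image metrics. Feature-classifier runs use
the narrow preset on ~380 planted patches (balanced plant frequencies
2:1:1:1:1 so every class appears in a 12-image set) for 6 epochs. Index-
refinement comparisons use 200 coarse stacks at 64×64. Mean per-image
Jaccard is the primary segmentation number, matching the challenge
convention of averaging per-image scores.

## Known limitations

* The `full` preset's exact layer table is an approximation of the deep
  architecture family; it is structurally faithful (RiR blocks, ~90
  weighted layers) but not layer-for-layer identical to any published
  configuration.
* The multiclass AUC reduction (unweighted mean of melanoma-vs-rest and
  seborrheic-keratosis-vs-rest, configurable to macro-over-3) is one of
  several defensible conventions; rank-based metrics make the choice
  immaterial for the comparisons made here.
* The CNN engine is single-threaded numpy; it is sized for 64–96 px
  desk-scale experiments, not for 320×320 training runs.
* Superpixel maps in feature fixtures are grid tiles rather than SLIC
  regions so that planted labels are exact; the SLIC path is exercised
  separately by the segmentation-free superpixel tests.
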