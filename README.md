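# dermlin

Desk-scale deep-learning pipelines for dermoscopy image analysis: joint
lesion segmentation and 3-way classification with a **Lesion Indexing
Network** (LIN), and 5-way dermoscopic-feature extraction with a **Lesion
Feature Network** (LFN). Everything runs on one CPU against synthetic
dermoscopy-like fixtures generated by the package itself, so the whole
pipeline is testable without downloading any clinical dataset.

## Who this is for

Researchers and students who want a small, fully inspectable implementation
of a dual-network lesion-analysis pipeline — including its data-balancing
augmentation, its distance-map-based classification refinement, and its
class-weighted loss — with every numerical claim backed by a test.

## The methods

**Lesion Indexing Network.** Two fully-convolutional residual
encoder–decoders (plain, bottleneck or Residual-in-Residual block families)
are trained on complementary augmentations of the same data: a
rotation-balanced dataset `DR` (each class rotated at a class-specific step
— 18° for melanoma and seborrheic keratosis, 45° for the much larger nevus
class — so class sizes equalize) and its randomly mirrored pair `DM`. At
test time each network scores the image at several scales; all score maps
are bilinearly interpolated back to the input resolution and summed. Each
network emits 4 per-pixel channels (background + 3 lesion categories), so
the fused maps give the segmentation mask (argmax ≠ background) and coarse
per-class maps `v_i` in one pass.

**Lesion Index Calculation Unit.** The coarse maps are normalized per pixel,

```
p_i(x,y) = (v_i − min_j v_j) / Σ_j (v_j − min_j v_j),
```

then weighted by a border-distance map `d` (Euclidean distance of each
lesion pixel to the nearest non-lesion or image-edge pixel, max-normalized
to 1) and averaged over the lesion area:

```
index_i ∝ mean over lesion pixels of p_i · d,   Σ_i index_i = 1.
```

Pixels near the border look skin-like and carry less class information;
down-weighting them measurably improves classification over a plain mean.

**Lesion Feature Network.** Images are subdivided into SLIC superpixels;
each superpixel's bounding box is cropped and resized to 56×56 and
classified into {background, pigment network, negative network, milia-like
cysts, streaks}. The trunk has 12 convolutions in 4 stages of (3×3, 1×1,
3×3) with batch normalization before every rectifier, max pooling after
stages 1–3 and global average pooling after stage 4. Training uses SGD
(lr 0.01, momentum 0.9, step decay 0.1) with a **class-weighted softmax
loss** — weights (1, 1, 5, 3, 8) for (B, PN, NN, MC, S) — to counter the
heavy background/pigment-network imbalance.

**Metrics.** Segmentation: accuracy, Jaccard (primary), Dice, sensitivity,
specificity. Classification and feature extraction: one-vs-rest ROC AUC
(primary) and average precision, with FPR = 1 − SP.

## Worked example

```python
from dermlin.synthetic_data import SynthSpec, generate_lesion_dataset
from dermlin.pipeline import train_lin_models, evaluate_lin
from dermlin.training import TrainConfig

train_items = generate_lesion_dataset(SynthSpec(n_per_class=(40, 40, 40), seed=0))
test_items = generate_lesion_dataset(SynthSpec(n_per_class=(10, 10, 10), seed=1))
cfg = TrainConfig(lr=0.01, momentum=0.9, batch_size=8, max_epochs=10, seed=0)
model_dr, model_dm, hist = train_lin_models(train_items, cfg, seed=0)
report = evaluate_lin([model_dr, model_dm], test_items, scales=[64, 96])
print({k: round(v, 3) for k, v in report["seg"].items()})
print("classification accuracy:", report["classification_accuracy"])
```

Output from this exact run:

```
{'AC': 0.971, 'JA': 0.83, 'DI': 0.903, 'SE': 0.835, 'SP': 0.999}
classification accuracy: 0.6666666666666666
```

meaning the tiny two-network ensemble, trained ten epochs on 120 synthetic
96×96 lesions, overlaps the true lesion masks of 30 held-out images at a
mean Jaccard of 0.83 and recovers the generator's lesion class on two
thirds of them (chance is one third).

The same pipeline is scriptable from the shell:

```bash
dermlin --seed 0 synth --n-per-class 40,40,40 --out-dir data/train
dermlin --seed 0 train-lin --in-dir data/train --epochs 10 --out ckpt/lin
dermlin predict-lin --checkpoints ckpt/lin_dr.npz ckpt/lin_dm.npz \
    --scales 64,96 --in-dir data/test/images \
    --out-mask-dir pred/masks --out-csv pred/predictions.csv
dermlin evaluate --task seg --pred-dir pred/masks --truth-dir data/test --out report.json
```

## Scope

The networks are built on a small self-contained numpy CNN engine
(`dermlin.nn`) with explicit backprop — deterministic, dependency-light and
sized for desk-scale experiments. The `full` depth preset reproduces the
~88-weighted-layer Residual-in-Residual architecture family structurally
but is not intended for CPU training; the `tiny` preset is the tested
workhorse. No DICOM support, no dataset download client, no GPU paths.
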