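import numpy as np
import pytest

from dermlin.networks import build_lfn
from dermlin.superpixels import compute_superpixels, extract_patch, predict_features, predicted_labels
from dermlin.types import LesionImage, SuperpixelMap


def _constant_image(side=64, value=0.5):
    return LesionImage(np.full((side, side, 3), value))


class TestComputeSuperpixels:
    def test_single_segment(self):
        sp = compute_superpixels(_constant_image(), n_segments=1)
        assert sp.n_segments == 1
        assert np.all(sp.labels == 0)

    def test_constant_image_degenerates_to_seeding_grid(self):
        sp = compute_superpixels(_constant_image(), n_segments=4)
        assert sp.n_segments == 4
        sizes = np.bincount(sp.labels.ravel())
        assert sizes.min() > 0.5 * sizes.max()  # roughly equal tiles

    def test_partition_property(self, small_lesion_items):
        image = small_lesion_items[0][0]
        sp = compute_superpixels(image, n_segments=30)
        # every pixel gets exactly one id from the contiguous range
        assert sp.labels.shape == image.shape
        assert set(np.unique(sp.labels)) == set(range(sp.n_segments))

    def test_count_tracks_request(self, small_lesion_items):
        image = small_lesion_items[0][0]
        sp = compute_superpixels(image, n_segments=50)
        assert 0.8 * 50 <= sp.n_segments <= 1.2 * 50

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            compute_superpixels(_constant_image(), n_segments=0)


class TestExtractPatch:
    def test_full_image_superpixel_is_whole_image(self):
        image = _constant_image(side=64, value=0.42)
        sp = SuperpixelMap(np.zeros((64, 64), int))
        patch = extract_patch(image, sp, 0)
        assert patch.pixels.shape == (56, 56, 3)
        assert np.allclose(patch.pixels, 0.42)

    def test_single_pixel_superpixel_constant_patch(self):
        image = _constant_image(side=16, value=0.3)
        image.pixels[5, 7] = [0.9, 0.1, 0.2]
        labels = np.zeros((16, 16), int)
        labels[5, 7] = 1
        patch = extract_patch(image, SuperpixelMap(labels), 1)
        assert np.allclose(patch.pixels, [0.9, 0.1, 0.2], atol=1e-12)

    def test_constant_square_region_mean_color(self):
        image = _constant_image(side=32, value=0.5)
        image.pixels[4:14, 6:16] = [0.2, 0.6, 0.8]
        labels = np.zeros((32, 32), int)
        labels[4:14, 6:16] = 1
        labels[0, 0] = 0  # id 0 fills the rest
        patch = extract_patch(image, SuperpixelMap(labels), 1)
        assert np.abs(patch.pixels.mean(axis=(0, 1)) - [0.2, 0.6, 0.8]).max() < 1e-6

    def test_box_crop_keeps_context(self):
        # an L-shaped superpixel: its bounding box includes outside pixels
        image = _constant_image(side=16, value=0.1)
        image.pixels[4:8, 4:8] = 0.9  # context inside the box but outside the sp
        labels = np.zeros((16, 16), int)
        labels[2:10, 2:4] = 1
        labels[2:4, 2:10] = 1
        patch = extract_patch(image, SuperpixelMap(labels), 1)
        assert patch.pixels.max() > 0.5  # context retained

    def test_unknown_id_rejected(self):
        image = _constant_image(side=16)
        with pytest.raises(ValueError, match="unknown"):
            extract_patch(image, SuperpixelMap(np.zeros((16, 16), int)), 3)


class TestPredictFeatures:
    def test_probabilities_sum_to_one(self, small_lesion_items):
        model = build_lfn("narrow", seed=0)
        image = small_lesion_items[0][0]
        sp = compute_superpixels(image, n_segments=9)
        probs = predict_features(model, image, sp)
        assert set(probs) == set(range(sp.n_segments))
        for p in probs.values():
            assert p.shape == (5,)
            assert p.sum() == pytest.approx(1.0)
            assert p.min() >= 0.0

    def test_matches_direct_patch_prediction(self, small_lesion_items):
        model = build_lfn("narrow", seed=1)
        model.set_training(False)
        image = small_lesion_items[1][0]
        sp = compute_superpixels(image, n_segments=4)
        probs = predict_features(model, image, sp)
        patch = extract_patch(image, sp, 2)
        scores = model.forward(patch.pixels.transpose(2, 0, 1)[None])[0]
        expected = np.exp(scores - scores.max())
        expected /= expected.sum()
        assert np.allclose(probs[2], expected)

    def test_planted_features_learned_above_chance(self):
        """Trained briefly on planted textures, the patch classifier recovers
        every feature class on held-out images with recall above the 0.2
        chance level of a 5-way problem."""
        from collections import defaultdict

        from dermlin.synthetic_data import SynthSpec, generate_feature_dataset
        from dermlin.training import LFN_CLASS_WEIGHTS, TrainConfig, train
        from dermlin.types import FEATURE_CLASSES

        freqs = {"B": 2.0, "PN": 1.0, "NN": 1.0, "MC": 1.0, "S": 1.0}
        spec = SynthSpec(n_per_class=(2, 2, 2), image_side=96, seed=0)
        images, spmaps, label_dicts = generate_feature_dataset(spec, freqs=freqs)
        samples = []
        for img, spmap, labels in zip(images, spmaps, label_dicts):
            for sp_id, label in labels.items():
                patch = extract_patch(img, spmap, sp_id)
                samples.append((patch.pixels.transpose(2, 0, 1), FEATURE_CLASSES.index(label)))
        model = build_lfn("narrow", seed=0)
        cfg = TrainConfig(lr=0.01, batch_size=32, max_epochs=6, seed=0,
                          class_weights=LFN_CLASS_WEIGHTS)
        model, _ = train(model, samples, cfg)

        held_out = SynthSpec(n_per_class=(1, 1, 1), image_side=96, seed=99)
        images2, spmaps2, labels2 = generate_feature_dataset(held_out, freqs=freqs)
        hit, tot = defaultdict(int), defaultdict(int)
        for img, spmap, labels in zip(images2, spmaps2, labels2):
            pred = predicted_labels(predict_features(model, img, spmap))
            for sp_id, label in labels.items():
                tot[label] += 1
                hit[label] += pred[sp_id] == label
        for cls in FEATURE_CLASSES:
            assert tot[cls] > 0
            assert hit[cls] / tot[cls] > 0.2, (cls, hit[cls], tot[cls])

    def test_hard_labels_are_argmax(self, small_lesion_items):
        model = build_lfn("narrow", seed=0)
        image = small_lesion_items[2][0]
        sp = compute_superpixels(image, n_segments=4)
        probs = predict_features(model, image, sp)
        labels = predicted_labels(probs)
        from dermlin.types import FEATURE_CLASSES

        for sp_id, p in probs.items():
            assert labels[sp_id] == FEATURE_CLASSES[int(np.argmax(p))]
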