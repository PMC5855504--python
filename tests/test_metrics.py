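import numpy as np
import pytest

from dermlin.metrics import (
    ConfusionCounts, average_precision, confusion, multiclass_auc, roc_auc, seg_metrics,
)
from dermlin.types import BinaryMask, LesionIndex


def brute_force_auc(scores, labels):
    """O(n²) rank statistic: P(s⁺ > s⁻) + ½ P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_ap(scores, labels):
    """Step-curve sweep: AP = Σ (R_k − R_{k−1}) · P_k over descending scores."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    ap, tp = 0.0, 0
    for k, l in enumerate(labels, start=1):
        if l == 1:
            tp += 1
            ap += (1.0 / n_pos) * (tp / k)
    return ap


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10), np.uint8)
        truth[:2, :5] = 1
        c = confusion(BinaryMask(truth), BinaryMask(truth))
        assert (c.ntp, c.ntn, c.nfp, c.nfn) == (10, 90, 0, 0)

    def test_inverted_prediction(self):
        truth = np.zeros((10, 10), np.uint8)
        truth[:2, :5] = 1
        c = confusion(BinaryMask(1 - truth), BinaryMask(truth))
        assert (c.ntp, c.ntn, c.nfp, c.nfn) == (0, 0, 90, 10)

    def test_counts_partition_all_pixels(self, rng):
        p = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        t = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        c = confusion(BinaryMask(p), BinaryMask(t))
        # exhaustive per-pixel tally
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for i in range(6):
            for j in range(6):
                key = {(1, 1): "tp", (0, 0): "tn", (1, 0): "fp", (0, 1): "fn"}[(p[i, j], t[i, j])]
                tally[key] += 1
        assert (c.ntp, c.ntn, c.nfp, c.nfn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )
        assert c.total == 36

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(BinaryMask(np.zeros((3, 3), np.uint8)),
                      BinaryMask(np.zeros((4, 4), np.uint8)))


class TestSegMetrics:
    def test_hand_evaluated_counts(self):
        m = seg_metrics(ConfusionCounts(3, 6, 0, 1))
        assert m["JA"] == pytest.approx(0.75)
        assert m["DI"] == pytest.approx(6 / 7)
        assert m["AC"] == pytest.approx(0.9)
        assert m["SE"] == pytest.approx(0.75)
        assert m["SP"] == pytest.approx(1.0)

    def test_perfect_prediction_all_ones(self):
        m = seg_metrics(ConfusionCounts(10, 90, 0, 0))
        assert all(v == 1.0 for v in m.values())

    def test_dice_jaccard_identity(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0 or tp + fn + fp == 0:
                continue
            m = seg_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m["DI"] == pytest.approx(2 * m["JA"] / (1 + m["JA"]))
            assert m["JA"] <= m["DI"] + 1e-12

    def test_fpr_equals_one_minus_sp(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 30, size=4))
            m = seg_metrics(ConfusionCounts(tp, tn, fp, fn))
            fpr = fp / (tn + fp)
            assert fpr == pytest.approx(1.0 - m["SP"])

    def test_undefined_metric_is_nan(self):
        m = seg_metrics(ConfusionCounts(0, 10, 0, 0))
        assert np.isnan(m["SE"])
        assert m["SP"] == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_identical_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_matches_rank_oracle_on_toy_sets(self, rng):
        for _ in range(20):
            scores = rng.random(6)
            labels = rng.integers(0, 2, size=6)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(12)
        labels = np.array([0, 1] * 6)
        assert roc_auc(np.exp(5 * scores), labels) == pytest.approx(roc_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestAveragePrecision:
    def test_all_positives_ranked_first(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("k,n", [(1, 5), (3, 5), (5, 5)])
    def test_single_positive_ranked_kth(self, k, n):
        scores = np.linspace(1.0, 0.1, n)
        labels = np.zeros(n, int)
        labels[k - 1] = 1
        assert average_precision(scores, labels) == pytest.approx(1.0 / k)

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(20):
            scores = rng.permutation(np.linspace(0.05, 0.95, 10))  # distinct scores
            labels = rng.integers(0, 2, size=10)
            if labels.sum() == 0:
                continue
            assert average_precision(scores, labels) == pytest.approx(
                brute_force_ap(scores, labels)
            )

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.4, 0.6], [0, 0])


def _index(v):
    return LesionIndex(index=np.asarray(v, dtype=float))


class TestMulticlassAuc:
    def test_perfect_indices(self):
        indices = [_index([1, 0, 0]), _index([0, 1, 0]), _index([0, 0, 1])] * 2
        truths = ["melanoma", "seborrheic_keratosis", "nevus"] * 2
        res = multiclass_auc(indices, truths)
        assert res["mean"] == 1.0

    def test_uniform_indices_chance_level(self):
        indices = [_index([1 / 3] * 3)] * 6
        truths = ["melanoma", "seborrheic_keratosis", "nevus"] * 2
        res = multiclass_auc(indices, truths)
        assert res["melanoma"] == pytest.approx(0.5)
        assert res["seborrheic_keratosis"] == pytest.approx(0.5)

    def test_mean_of_binary_oracles_on_toy_set(self, rng):
        indices = [_index(x / x.sum()) for x in rng.random((9, 3)) + 0.05]
        truths = [["melanoma", "seborrheic_keratosis", "nevus"][i % 3] for i in range(9)]
        res = multiclass_auc(indices, truths)
        for k, cls in [(0, "melanoma"), (1, "seborrheic_keratosis")]:
            scores = [li.index[k] for li in indices]
            labels = [1 if t == cls else 0 for t in truths]
            assert res[cls] == pytest.approx(brute_force_auc(scores, labels))
        assert res["mean"] == pytest.approx(
            (res["melanoma"] + res["seborrheic_keratosis"]) / 2
        )

    def test_macro_three_class_option(self, rng):
        indices = [_index(x / x.sum()) for x in rng.random((6, 3)) + 0.05]
        truths = [["melanoma", "seborrheic_keratosis", "nevus"][i % 3] for i in range(6)]
        res = multiclass_auc(indices, truths,
                             scored_classes=("melanoma", "seborrheic_keratosis", "nevus"))
        assert set(res) == {"melanoma", "seborrheic_keratosis", "nevus", "mean"}
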