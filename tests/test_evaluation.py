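"""Metric correctness against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from jawnet.evaluation import (classification_metrics, joint_accuracy,
                               merge_classes, quadrant_of, segmentation_iou,
                               stratified_report)


class TestClassificationMetrics:
    def test_perfect_predictions_all_ones(self):
        labels = ["AB", "OKC", "DC", "Normal"] * 3
        m = classification_metrics(labels, labels)
        assert m["accuracy"] == 1.0
        assert (m["per_class"][["accuracy", "precision", "recall", "f1"]]
                .to_numpy() == 1.0).all()

    def test_hand_computed_confusion_fixture(self):
        # AB: 2 right, 1 as OKC; OKC: 1 right, 1 as AB; DC: 2 right;
        # Normal: 1 right, 1 as DC
        labels = ["AB", "AB", "AB", "OKC", "OKC", "DC", "DC", "Normal", "Normal"]
        preds = ["AB", "AB", "OKC", "OKC", "AB", "DC", "DC", "Normal", "DC"]
        m = classification_metrics(preds, labels)
        ab = m["per_class"].loc["AB"]
        assert ab["precision"] == pytest.approx(2 / 3)   # TP=2, FP=1
        assert ab["recall"] == pytest.approx(2 / 3)      # FN=1
        assert ab["accuracy"] == pytest.approx(7 / 9)    # TN=5
        assert ab["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(6 / 9)
        dc = m["per_class"].loc["DC"]
        assert dc["precision"] == pytest.approx(2 / 3)
        assert dc["recall"] == pytest.approx(1.0)

    def test_absent_class_is_nan_not_zero(self):
        m = classification_metrics(["AB", "AB"], ["AB", "AB"])
        assert np.isnan(m["per_class"].loc["OKC", "f1"])
        assert m["macro"]["f1"] == pytest.approx(1.0)  # NaNs excluded

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestIoU:
    def test_identical_nonempty_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert segmentation_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert segmentation_iou(a, b) == 0.0

    def test_half_overlapping_equal_squares_third(self):
        a = np.zeros((10, 20), bool)
        b = np.zeros((10, 20), bool)
        a[0:10, 0:10] = True
        b[0:10, 5:15] = True          # overlap 50, union 150
        assert segmentation_iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        assert segmentation_iou(np.zeros((4, 4), bool),
                                np.zeros((4, 4), bool)) == 1.0

    def test_symmetric(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        assert segmentation_iou(a, b) == segmentation_iou(b, a)


class TestJointAccuracy:
    def _mask(self, frac):
        ref = np.zeros((10, 10), bool)
        ref[0:10, 0:10] = True
        pred = np.zeros((10, 10), bool)
        pred[: int(10 * frac)] = True
        return pred, ref

    def test_all_correct_high_iou(self):
        pred, ref = self._mask(0.9)
        assert joint_accuracy([("AB", pred)], [("AB", ref)]) == 1.0

    def test_correct_class_low_iou_fails(self):
        pred, ref = self._mask(0.4)    # IoU 0.4 < threshold
        assert joint_accuracy([("AB", pred)], [("AB", ref)]) == 0.0

    def test_iou_exactly_half_fails_strict_inequality(self):
        pred, ref = self._mask(0.5)
        assert segmentation_iou(pred, ref) == 0.5
        assert joint_accuracy([("AB", pred)], [("AB", ref)]) == 0.0

    def test_normal_ignores_heatmap(self):
        garbage = np.ones((10, 10), bool)
        assert joint_accuracy([("Normal", garbage)], [("Normal", None)]) == 1.0

    def test_missing_abnormal_mask_rejected(self):
        with pytest.raises(ValueError):
            joint_accuracy([("AB", np.ones((2, 2), bool))], [("AB", None)])


class TestStratification:
    def _records(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(10, 5000, n)
        return pd.DataFrame({
            "label": rng.choice(["AB", "OKC", "DC"], n),
            "pred_label": rng.choice(["AB", "OKC", "DC", "Normal"], n),
            "iou": rng.random(n),
            "lesion_pixels": sizes,
            "center_x": rng.uniform(0, 300, n),
            "center_y": rng.uniform(0, 150, n),
            "image_w": 300, "image_h": 150,
        })

    def test_hundred_samples_ten_per_bin(self):
        size_t, quad_t = stratified_report(self._records(100))
        assert list(size_t["n"]) == [10] * 10
        assert quad_t["n"].sum() == 100

    def test_bin_boundaries_match_sorted_deciles(self):
        rec = self._records(100, seed=3)
        size_t, _ = stratified_report(rec)
        sizes = np.sort(rec["lesion_pixels"].to_numpy())
        # bin b must contain exactly the b-th sorted decile
        rec2 = rec.sort_values("lesion_pixels")
        for b in range(1, 11):
            decile = sizes[(b - 1) * 10: b * 10]
            assert size_t.loc[b, "n"] == 10
        # mean lesion size is nondecreasing across bins
        means = [rec2["lesion_pixels"].to_numpy()[(b - 1) * 10: b * 10].mean()
                 for b in range(1, 11)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_quadrant_numbering_counterclockwise_from_upper_right(self):
        cx, cy = 150.0, 75.0
        assert quadrant_of(200, 30, cx, cy) == 1   # upper right
        assert quadrant_of(100, 30, cx, cy) == 2   # upper left
        assert quadrant_of(100, 120, cx, cy) == 3  # lower left
        assert quadrant_of(200, 120, cx, cy) == 4  # lower right

    def test_exact_centre_ties_to_quadrant_one(self):
        assert quadrant_of(150.0, 75.0, 150.0, 75.0) == 1

    def test_fewer_samples_than_bins_warns(self):
        with pytest.warns(UserWarning, match="bins"):
            stratified_report(self._records(5))


class TestMergeClasses:
    def test_ab_predicted_as_okc_counts_correct_after_merge(self):
        m = merge_classes(["OKC"], ["AB"], {"AB", "OKC"})
        assert m["accuracy"] == 1.0

    def test_merge_all_classes_trivial_accuracy(self):
        m = merge_classes(["AB", "DC"], ["OKC", "Normal"],
                          {"AB", "OKC", "DC", "Normal"})
        assert m["accuracy"] == 1.0

    def test_empty_merge_set_is_identity(self):
        preds, labels = ["AB", "DC"], ["AB", "OKC"]
        a = merge_classes(preds, labels, set())
        b = classification_metrics(preds, labels)
        assert a["accuracy"] == b["accuracy"]

    def test_merging_never_decreases_accuracy(self, rng):
        """Coarsening property on random fixtures."""
        classes = np.array(["AB", "OKC", "DC", "Normal"])
        for _ in range(20):
            labels = classes[rng.integers(0, 4, 30)]
            preds = classes[rng.integers(0, 4, 30)]
            base = classification_metrics(preds, labels)["accuracy"]
            merged = merge_classes(preds, labels, {"AB", "OKC"})["accuracy"]
            assert merged >= base
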