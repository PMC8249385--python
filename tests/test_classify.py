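"""Classifier training contracts, ROC/AUC and report comparison."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from polsynth import classify
from polsynth.errors import ConfigurationError


def backbone_checksum(backbone):
    h = hashlib.sha256()
    for a in backbone.state_arrays():
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def separable_tiles(rng, n, side=16):
    """Tiles whose spatial pattern encodes the class.

    Instance normalization in the backbone removes global brightness,
    so the class cue is geometric: a bright band across the top half
    (cancer) versus the left half (normal).
    """
    tiles, labels = [], []
    for i in range(n):
        label = "cancer" if i % 2 else "normal"
        img = rng.normal(40, 8, (side, side))
        if label == "cancer":
            img[: side // 2, :] += 150
        else:
            img[:, : side // 2] += 150
        tiles.append(np.clip(img, 0, 255))
        labels.append(label)
    return tiles, labels


class TestSplitForClassifier:
    def test_ten_items_split_6_3_1(self):
        manifest = pd.DataFrame({"tile_id": range(10)})
        part = classify.split_for_classifier(manifest, seed=0)
        counts = part.value_counts().to_dict()
        assert counts == {"train": 6, "test": 3, "validation": 1}

    def test_study_scale_test_count(self):
        manifest = pd.DataFrame({"tile_id": range(4414)})
        part = classify.split_for_classifier(manifest, seed=0)
        assert (part == "test").sum() == 1324  # floor(4414 * 0.3)

    @pytest.mark.parametrize("n", [10, 37, 101, 1000])
    def test_disjoint_exhaustive(self, n):
        manifest = pd.DataFrame({"tile_id": range(n)})
        part = classify.split_for_classifier(manifest, seed=n)
        assert len(part) == n and not part.isna().any()
        assert (part == "test").sum() == (3 * n) // 10
        assert (part == "validation").sum() == n // 10

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            classify.split_for_classifier(pd.DataFrame({"tile_id": []}))


class TestTrainClassifier:
    def test_frozen_backbone_bitwise_unchanged(self, rng):
        tiles, labels = separable_tiles(rng, 24)
        spec = classify.ClassifierSpec(epochs=2)
        clf = classify.train_classifier(tiles[:16], labels[:16], tiles[16:],
                                        labels[16:], spec, seed=0)
        before = backbone_checksum(
            classify.ResidualBackbone(spec, np.random.default_rng(
                np.random.default_rng(0).integers(2**31))))
        assert backbone_checksum(clf.backbone) == before

    def test_separable_task_reaches_high_training_accuracy(self, rng):
        tiles, labels = separable_tiles(rng, 40)
        spec = classify.ClassifierSpec(epochs=12)
        clf = classify.train_classifier(tiles[:32], labels[:32], tiles[32:],
                                        labels[32:], spec, seed=1)
        scores = clf.predict_scores(tiles[:32])
        pred = scores >= 0.5
        truth = np.array([l == "cancer" for l in labels[:32]])
        assert (pred == truth).mean() >= 0.95
        assert clf.best_val_accuracy >= 0.8

    def test_two_seeds_wellformed_reports(self, rng):
        tiles, labels = separable_tiles(rng, 20)
        for seed in (0, 1):
            clf = classify.train_classifier(
                tiles[:14], labels[:14], tiles[14:], labels[14:],
                classify.ClassifierSpec(epochs=2), seed=seed)
            rep = classify.build_validation_report(clf, tiles[14:], labels[14:])
            rep.validate()

    def test_single_class_rejected(self, rng):
        tiles, _ = separable_tiles(rng, 8)
        with pytest.raises(ValueError):
            classify.train_classifier(tiles, ["cancer"] * 8, tiles,
                                      ["cancer"] * 8)

    def test_pretrained_init_unavailable(self):
        with pytest.raises(ConfigurationError):
            classify.ClassifierSpec(init="pretrained").validate()


class TestRocAuc:
    def test_perfect_separation(self):
        pts, auc = classify.roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_inverted_scores(self):
        _, auc = classify.roc_and_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert auc == 0.0

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.uniform(0, 1, n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            pts, auc = classify.roc_and_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            mw = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc == pytest.approx(mw, abs=1e-12)
            arr = np.asarray(pts)
            assert (np.diff(arr[:, 0]) >= 0).all()
            assert (np.diff(arr[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify.roc_and_auc([0.1, 0.9], [1, 1])


class TestActivations:
    def test_shape_and_duplicate_rows(self, rng):
        tiles, labels = separable_tiles(rng, 12)
        clf = classify.train_classifier(tiles[:8], labels[:8], tiles[8:],
                                        labels[8:],
                                        classify.ClassifierSpec(epochs=1),
                                        seed=0)
        acts = classify.extract_activations(clf, [tiles[0], tiles[0], tiles[1]])
        assert acts.shape == (3, 512)
        np.testing.assert_array_equal(acts[0], acts[1])

    def test_head_logits_are_linear_in_activations(self, rng):
        tiles, labels = separable_tiles(rng, 12)
        clf = classify.train_classifier(tiles[:8], labels[:8], tiles[8:],
                                        labels[8:],
                                        classify.ClassifierSpec(epochs=1),
                                        seed=0)
        acts = classify.extract_activations(clf, tiles[:4])
        expected = acts @ clf.head.weight.data + clf.head.bias.data
        np.testing.assert_allclose(clf.logits(tiles[:4]), expected, atol=1e-6)


class TestCompareReports:
    def _report(self, rng, seed=0):
        tiles, labels = separable_tiles(rng, 20)
        clf = classify.train_classifier(tiles[:14], labels[:14], tiles[14:],
                                        labels[14:],
                                        classify.ClassifierSpec(epochs=2),
                                        seed=seed)
        return classify.build_validation_report(clf, tiles[14:], labels[14:],
                                                tile_ids=list(range(6)))

    def test_identical_reports_zero_delta(self, rng):
        rep = self._report(rng)
        out = classify.compare_real_vs_synthetic(rep, rep)
        assert out["delta_auc"] == 0.0
        assert out["agreement"] == 1.0

    def test_mismatched_test_sets_rejected(self, rng):
        rep_a = self._report(rng)
        rep_b = self._report(rng)
        rep_b.per_item["tile_id"] = rep_b.per_item["tile_id"] + 100
        with pytest.raises(ValueError):
            classify.compare_real_vs_synthetic(rep_a, rep_b)
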