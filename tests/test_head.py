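"""Transfer head: training mechanics, evaluation, relabelling."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import scribbleprobe as sp
from scribbleprobe.data import DrawingImage, LabeledDataset
from scribbleprobe.head import (
    ConfusionMatrix,
    _init_params,
    _train_batch,
    pooled_features,
)
from scribbleprobe.synthetic import DEFAULT_CLASS_COUNTS


def _tiny_dataset(n_per_class=2, seed=0):
    params = sp.make_season_params("paperlike")
    return sp.generate_dataset(params, {s: n_per_class for s in sp.SEASONS},
                               seed=seed)


@pytest.fixture(scope="module")
def tiny_train_val(backbone):
    ds = _tiny_dataset(3)
    train, val = sp.split_train_val(ds, sp.SplitSpec(8, 4, seed=0))
    return train, val


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self, backbone,
                                                         tiny_train_val):
        train, val = tiny_train_val
        cfg = sp.HeadConfig(n_classes=4, lr=0.0, max_epochs=3, seed=0,
                            augment=False)
        rng = np.random.default_rng(cfg.seed)
        init = _init_params(rng, cfg)
        model, _ = sp.train_head(backbone, train, val, cfg)
        for key in ("W1", "b1", "W2", "b2", "gamma", "beta"):
            assert np.array_equal(model.params[key], init[key]), key

    def test_gradients_match_finite_differences(self):
        """SGD step against numerical gradients of the full head loss."""
        cfg = sp.HeadConfig(n_classes=3, fc_width=6, dropout_rate=0.0,
                            lr=1e-3, l2_strength=0.05, seed=0)
        rng = np.random.default_rng(0)
        params = _init_params(rng, cfg)
        X = rng.normal(size=(5, 512))
        y = np.array([0, 1, 2, 0, 1])

        def loss_at(p):
            mu, var = X.mean(0), X.var(0)
            xhat = (X - mu) / np.sqrt(var + 1e-5)
            z = xhat * p["gamma"] + p["beta"]
            h = np.maximum(z @ p["W1"] + p["b1"], 0.0)
            logits = h @ p["W2"] + p["b2"]
            logits = logits - logits.max(axis=1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
            ce = -logp[np.arange(5), y].mean()
            return ce + cfg.l2_strength * np.sum(p["W1"] ** 2)

        before = {k: v.copy() for k, v in params.items()}
        _train_batch(params, X, y, cfg, np.random.default_rng(1))
        for key, idx in [("W2", (2, 1)), ("b2", (0,)), ("gamma", (3,)),
                         ("W1", (10, 2))]:
            analytic = (before[key][idx] - params[key][idx]) / cfg.lr
            eps = 1e-6
            probe = {k: v.copy() for k, v in before.items()}
            probe[key][idx] += eps
            up = loss_at(probe)
            probe[key][idx] -= 2 * eps
            down = loss_at(probe)
            numeric = (up - down) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=2e-3, abs=1e-6), key

    def test_early_stopping_keeps_best_epoch(self, backbone, tiny_train_val):
        train, val = tiny_train_val
        cfg = sp.HeadConfig(n_classes=4, max_epochs=12, patience_epochs=2,
                            seed=1, augment=False)
        model, hist = sp.train_head(backbone, train, val, cfg)
        best = hist.attrs["best_epoch"]
        accs = hist["val_accuracy"].to_numpy()
        assert accs[best] == accs.max()
        # training stops within patience of the last improvement
        assert len(hist) <= best + cfg.patience_epochs + 1
        acc, _ = sp.evaluate(model, val)
        assert acc == pytest.approx(accs[best])

    def test_frozen_backbone_weights_untouched(self, backbone, tiny_train_val):
        train, val = tiny_train_val
        snapshot = {i: backbone.conv_weights(i)[0].copy() for i in (1, 8, 16)}
        cfg = sp.HeadConfig(n_classes=4, max_epochs=2, seed=0, augment=False)
        sp.train_head(backbone, train, val, cfg)
        for i, w in snapshot.items():
            assert np.array_equal(backbone.conv_weights(i)[0], w)

    def test_augmented_features_only_for_training_stream(self, backbone,
                                                         tiny_train_val):
        """The cache records flipped variants for train ids only."""
        train, val = tiny_train_val
        cache = {}
        cfg = sp.HeadConfig(n_classes=4, max_epochs=1, seed=0, augment=True)
        sp.train_head(backbone, train, val, cfg, feature_cache=cache)
        for im in train:
            assert (im.id, True) in cache
        for im in val:
            assert (im.id, False) in cache and (im.id, True) not in cache

    def test_flip_variants_differ(self, backbone, tiny_train_val):
        train, _ = tiny_train_val
        feats = pooled_features(backbone, [train[0]], flips=True)
        assert feats.shape == (1, 4, 512)
        assert not np.allclose(feats[0, 0], feats[0, 1])

    def test_label_mismatch_rejected(self, backbone, tiny_train_val):
        train, val = tiny_train_val
        cfg = sp.HeadConfig(n_classes=3, seed=0)
        with pytest.raises(ValueError, match="n_classes"):
            sp.train_head(backbone, train, val, cfg)

    def test_empty_split_rejected(self, backbone, tiny_train_val):
        train, _ = tiny_train_val
        empty = LabeledDataset((), seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            sp.train_head(backbone, train, empty, sp.HeadConfig(n_classes=4))


class TestEvaluate:
    def test_perfect_predictor_diagonal(self, paperlike_small):
        model = SimpleNamespace(
            classes=tuple(sorted(set(paperlike_small.labels))),
            predict=lambda ds: ds.labels,
        )
        acc, cm = sp.evaluate(model, paperlike_small)
        assert acc == 1.0
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)

    def test_rows_sum_to_class_counts(self, paperlike_small):
        rng = np.random.default_rng(0)
        classes = tuple(sorted(set(paperlike_small.labels)))
        model = SimpleNamespace(
            classes=classes,
            predict=lambda ds: rng.choice(classes, size=len(ds)),
        )
        _, cm = sp.evaluate(model, paperlike_small)
        counts = paperlike_small.class_counts
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == counts[c]

    def test_unseen_label_rejected(self, paperlike_small):
        model = SimpleNamespace(classes=("autumn", "spring"),
                                predict=lambda ds: ds.labels)
        with pytest.raises(ValueError, match="unseen"):
            sp.evaluate(model, paperlike_small)

    def test_confusion_matrix_validation(self):
        with pytest.raises(ValueError, match="square"):
            ConfusionMatrix(np.zeros((2, 3)), ("a", "b"))


class TestRelabel:
    def _counts_dataset(self):
        images = tuple(
            DrawingImage(np.full((224, 224, 3), 245, dtype=np.uint8),
                         label=season, id=f"{season}-{i}")
            for season, n in DEFAULT_CLASS_COUNTS.items() for i in range(n)
        )
        return LabeledDataset(images, seed=0)

    def test_cold_warm_grouping_sums_printed_counts(self):
        """autumn+winter -> 746 drawings, spring+summer -> 553."""
        ds = self._counts_dataset()
        grouped = sp.relabel(ds, {"autumn": "cold", "winter": "cold",
                                  "spring": "warm", "summer": "warm"})
        assert grouped.class_counts == {"cold": 746, "warm": 553}
        assert len(grouped) == len(ds)

    def test_identity_grouping_no_change(self, paperlike_small):
        same = sp.relabel(paperlike_small,
                          {s: s for s in sp.SEASONS})
        assert list(same.labels) == list(paperlike_small.labels)

    def test_missing_label_rejected(self, paperlike_small):
        with pytest.raises(KeyError, match="autumn"):
            sp.relabel(paperlike_small, {"spring": "x", "summer": "x",
                                         "winter": "x"})
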