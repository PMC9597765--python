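"""Transfer-learning head on the frozen backbone.

Architecture: global average pooling of the last conv layer's feature maps
(512 values) -> batch normalisation -> fully connected layer of width 2048
with L2 penalty 0.1 -> dropout 0.2 -> softmax output, trained with SGD
(learning rate 0.1, batch size 16) under categorical cross-entropy, with
early stopping after 3 epochs without validation-accuracy improvement and
horizontal/vertical flip augmentation of the training stream.

Because the backbone is frozen, pooled features (and their flipped
variants) are computed once and cached; training then touches only the
head parameters, which makes the procedure exactly equivalent to training
the head on top of the network while being desk-scale on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .backbone import Backbone
from .data import DrawingImage, LabeledDataset

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class HeadConfig:
    """Hyper-parameters of the classification head (defaults = the study's)."""

    n_classes: int = 4
    fc_width: int = 2048
    l2_strength: float = 0.1
    dropout_rate: float = 0.2
    lr: float = 0.1
    batch_size: int = 16
    patience_epochs: int = 3
    max_epochs: int = 50
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.lr < 0 or self.l2_strength < 0:
            raise ValueError("lr and l2_strength must be >= 0")
        if min(self.fc_width, self.batch_size, self.max_epochs, self.n_classes) < 1:
            raise ValueError("fc_width/batch_size/max_epochs/n_classes must be >= 1")


@dataclass
class ConfusionMatrix:
    """Row = true label, column = predicted label."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise ValueError("counts must be a square non-negative matrix")
        self.counts = c.astype(int)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def pooled_features(
    backbone: Backbone,
    images: Sequence[DrawingImage],
    flips: bool = False,
) -> np.ndarray:
    """Global-average-pooled last-conv features, (n, 512) or (n, 4, 512).

    With ``flips=True`` the four flip variants (identity, horizontal,
    vertical, both) are each pushed through the backbone — flipping does
    not commute with convolution, so augmented features must be extracted,
    not mirrored.
    """
    feats = []
    for im in images:
        px = im.pixels
        variants = [px]
        if flips:
            variants += [px[:, ::-1], px[::-1, :], px[::-1, ::-1]]
        rows = [
            backbone.forward(v, layers=("conv16",))["conv16"].mean(axis=(0, 1))
            for v in variants
        ]
        feats.append(np.stack(rows) if flips else rows[0])
    return np.stack(feats).astype(np.float32)


def _cached_pooled(backbone, images, flips: bool, cache: Optional[dict]):
    if cache is None:
        return pooled_features(backbone, images, flips=flips)
    rows = []
    for im in images:
        key = (im.id, flips)
        if key not in cache:
            cache[key] = pooled_features(backbone, [im], flips=flips)[0]
        rows.append(cache[key])
    return np.stack(rows)


class HeadModel:
    """Trained head; predicts labels from images via the frozen backbone."""

    def __init__(self, params: dict, classes: tuple[str, ...],
                 config: HeadConfig, backbone: Backbone):
        self.params = params
        self.classes = classes
        self.config = config
        self.backbone = backbone

    # -- inference -------------------------------------------------------
    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        xhat = (X - p["running_mean"]) / np.sqrt(p["running_var"] + _BN_EPS)
        z = xhat * p["gamma"] + p["beta"]
        h = np.maximum(z @ p["W1"] + p["b1"], 0.0)
        return h @ p["W2"] + p["b2"]

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        logits = self._forward_eval(np.asarray(X, dtype=np.float64))
        return np.asarray(self.classes)[np.argmax(logits, axis=1)]

    def predict(self, dataset: LabeledDataset) -> np.ndarray:
        X = pooled_features(self.backbone, list(dataset))
        return self.predict_features(X)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(rng: np.random.Generator, config: HeadConfig) -> dict:
    d_in = 512
    return {
        "gamma": np.ones(d_in),
        "beta": np.zeros(d_in),
        "running_mean": np.zeros(d_in),
        "running_var": np.ones(d_in),
        "W1": rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, config.fc_width)),
        "b1": np.zeros(config.fc_width),
        "W2": rng.normal(
            0, np.sqrt(2.0 / config.fc_width), size=(config.fc_width, config.n_classes)
        ),
        "b2": np.zeros(config.n_classes),
    }


def _train_batch(params: dict, X: np.ndarray, Y: np.ndarray,
                 config: HeadConfig, rng: np.random.Generator) -> float:
    """One SGD step (train-mode batch-norm, inverted dropout); returns loss."""
    m = X.shape[0]
    mu = X.mean(axis=0)
    var = X.var(axis=0)
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xc = X - mu
    xhat = xc * inv
    z = xhat * params["gamma"] + params["beta"]
    a1 = z @ params["W1"] + params["b1"]
    h = np.maximum(a1, 0.0)
    if config.dropout_rate > 0:
        mask = (rng.random(h.shape) >= config.dropout_rate) / (
            1.0 - config.dropout_rate
        )
        hd = h * mask
    else:
        mask = None
        hd = h
    logits = hd @ params["W2"] + params["b2"]
    probs = _softmax(logits)
    eps = 1e-12
    ce = -np.mean(np.log(probs[np.arange(m), Y] + eps))
    loss = ce + config.l2_strength * np.sum(params["W1"] ** 2)

    # backward
    dlogits = probs.copy()
    dlogits[np.arange(m), Y] -= 1.0
    dlogits /= m
    dW2 = hd.T @ dlogits
    db2 = dlogits.sum(axis=0)
    dhd = dlogits @ params["W2"].T
    dh = dhd * mask if mask is not None else dhd
    da1 = dh * (a1 > 0)
    dW1 = z.T @ da1 + 2.0 * config.l2_strength * params["W1"]
    db1 = da1.sum(axis=0)
    dz = da1 @ params["W1"].T
    dgamma = (dz * xhat).sum(axis=0)
    dbeta = dz.sum(axis=0)
    # batch-norm backward (through the batch statistics)
    dxhat = dz * params["gamma"]
    dx = (inv / m) * (
        m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )
    del dx  # inputs are frozen features; gradient stops here

    lr = config.lr
    params["W1"] -= lr * dW1
    params["b1"] -= lr * db1
    params["W2"] -= lr * dW2
    params["b2"] -= lr * db2
    params["gamma"] -= lr * dgamma
    params["beta"] -= lr * dbeta
    params["running_mean"] = (
        _BN_MOMENTUM * params["running_mean"] + (1 - _BN_MOMENTUM) * mu
    )
    params["running_var"] = (
        _BN_MOMENTUM * params["running_var"] + (1 - _BN_MOMENTUM) * var
    )
    return float(loss)


def train_head(
    backbone: Backbone,
    train: LabeledDataset,
    val: LabeledDataset,
    config: HeadConfig,
    feature_cache: Optional[dict] = None,
) -> tuple[HeadModel, pd.DataFrame]:
    """Train the head on frozen pooled features; return best-val model + history.

    The convolutional weights are never touched. Flip augmentation applies
    to the training stream only; validation images are evaluated unflipped.
    Early stopping keeps the parameters of the epoch with the highest
    validation accuracy and stops after ``patience_epochs`` epochs without
    improvement.

    ``feature_cache`` (a dict, shared across calls) memoises pooled
    features per image id; because the backbone is frozen, features are
    independent of the training seed, so repeated trainings on the same
    data cost only the head updates.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val must be non-empty")
    classes = tuple(sorted(set(train.labels)))
    if len(classes) != config.n_classes:
        raise ValueError(
            f"n_classes={config.n_classes} but training labels are {classes}"
        )
    if not set(val.labels) <= set(classes):
        raise ValueError("validation labels unseen in training")

    class_index = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([class_index[l] for l in train.labels])
    Xtr = _cached_pooled(backbone, list(train), config.augment, feature_cache)
    Xval = _cached_pooled(backbone, list(val), False, feature_cache)
    y_val = val.labels

    rng = np.random.default_rng(config.seed)
    params = _init_params(rng, config)
    best = {k: v.copy() for k, v in params.items()}
    best_acc = -np.inf
    best_epoch = -1
    history = []
    since_improve = 0
    n = len(train)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.augment:
                variant = rng.integers(0, Xtr.shape[1], size=len(idx))
                xb = Xtr[idx, variant].astype(np.float64)
            else:
                xb = Xtr[idx].astype(np.float64)
            losses.append(_train_batch(params, xb, y_tr[idx], config, rng))
        model = HeadModel(params, classes, config, backbone)
        val_acc = float(np.mean(model.predict_features(Xval) == y_val))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_accuracy": val_acc}
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience_epochs:
                break

    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return HeadModel(best, classes, config, backbone), hist


def evaluate(
    model: HeadModel, dataset: LabeledDataset
) -> tuple[float, ConfusionMatrix]:
    """Accuracy and confusion matrix of the model on a labelled dataset."""
    unseen = sorted(set(dataset.labels) - set(model.classes))
    if unseen:
        raise ValueError(f"labels unseen at training time: {unseen}")
    pred = model.predict(dataset)
    counts = _sk_confusion(dataset.labels, pred, labels=list(model.classes))
    cm = ConfusionMatrix(counts=counts, labels=model.classes)
    return cm.accuracy, cm


def relabel(dataset: LabeledDataset, grouping: Mapping[str, str]) -> LabeledDataset:
    """Merge classes by mapping old labels to new ones (counts are summed)."""
    return dataset.map_labels(grouping)
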