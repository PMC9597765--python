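"""Gram-matrix style probing of convolutional layers.

The style (texture) of an image at a conv layer is summarised by the Gram
matrix ``G = F^T F``, where the columns of ``F`` are the layer's C
flattened feature maps: ``G[i, j]`` is the inner product of maps i and j,
an (un-normalised) correlation of the two filters' responses. Flattened
Gram matrices are classified with the same PCA + SVM machinery as the
content probes. FC layers carry no feature maps, so no Gram matrix exists
for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .backbone import CONV_LAYERS, FC_LAYERS, Backbone, layer_shape
from .content import LayerProbeResult, pca_scores_fixed, probe_feature_matrix
from .data import DrawingImage, LabeledDataset


def gram_matrix(feature_maps) -> np.ndarray:
    """C x C matrix of inner products between flattened feature maps.

    Accepts a (C, N) array, a (C, H, W) tensor, or a list of equal-length
    1-D maps. No normalisation by map size or channel count is applied
    (an option for that lives in :func:`gram_feature_vector`).
    """
    if isinstance(feature_maps, np.ndarray):
        maps = feature_maps.reshape(feature_maps.shape[0], -1)
    else:
        rows = [np.asarray(m, dtype=float).ravel() for m in feature_maps]
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"feature maps have unequal lengths: {sorted(lengths)}")
        maps = np.stack(rows)
    if maps.shape[1] < 1:
        raise ValueError("feature maps must be non-empty")
    maps64 = maps.astype(np.float64, copy=False)
    return maps64 @ maps64.T


def gram_feature_vector(
    image: DrawingImage,
    backbone: Backbone,
    layer_id: str,
    normalize=None,
) -> np.ndarray:
    """Row-major flattening of the layer's Gram matrix (length C^2).

    ``normalize`` options: ``None`` (plain ``F^T F``, the study protocol),
    ``"size"`` (divide by the map size N, the style-transfer convention) or
    ``"unit"`` (scale each image's flattened Gram vector to unit L2 norm,
    removing the overall ink-energy magnitude and keeping only the relative
    co-activation structure).
    """
    G = _gram_from_forward(backbone.forward(_check_conv(image, layer_id),
                                            layers=(layer_id,))[layer_id],
                           normalize)
    return G.ravel()


def _check_conv(image: DrawingImage, layer_id: str) -> np.ndarray:
    if layer_id in FC_LAYERS:
        raise ValueError(
            f"Gram matrices cannot be computed for FC layer {layer_id!r}: "
            "FC activations are vectors, not feature maps"
        )
    if layer_id not in CONV_LAYERS:
        raise ValueError(f"unknown conv layer {layer_id!r}")
    return image.pixels


def _gram_from_forward(act: np.ndarray, normalize=None) -> np.ndarray:
    maps = np.ascontiguousarray(act.transpose(2, 0, 1)).reshape(act.shape[2], -1)
    G = gram_matrix(maps)
    if normalize == "size":
        G = G / maps.shape[1]
    elif normalize == "unit":
        nrm = np.linalg.norm(G)
        if nrm > 0:
            G = G / nrm
    elif normalize not in (None, False):
        raise ValueError("normalize must be None, 'size' or 'unit'")
    return G


def gram_feature_matrix(
    dataset: LabeledDataset,
    backbone: Backbone,
    layers: Sequence[str],
    normalize=None,
) -> dict[str, np.ndarray]:
    """Per-layer (n_images, C^2) matrices of flattened Gram vectors."""
    for l in layers:
        if l not in CONV_LAYERS:
            raise ValueError(f"Gram features exist only for conv layers, got {l!r}")
    out: dict[str, list[np.ndarray]] = {l: [] for l in layers}
    for im in dataset:
        acts = backbone.forward(im.pixels, layers=layers)
        for l in layers:
            out[l].append(
                _gram_from_forward(acts[l], normalize).ravel().astype(np.float32)
            )
    return {l: np.stack(v) for l, v in out.items()}


def gram_probe_layers(
    dataset: LabeledDataset,
    backbone: Backbone,
    layers: Sequence[str] = CONV_LAYERS,
    target_variance: float = 0.80,
    n_folds: int = 10,
    seed: int = 0,
    normalize=None,
    leakage_free: bool = False,
) -> list[LayerProbeResult]:
    """Gram-matrix probe per conv layer (feature_type = 'gram', RGB images).

    The default (``normalize=None``) is the plain ``F^T F`` protocol;
    ``normalize='unit'`` probes the energy-free co-activation structure,
    which is the appropriate setting when classes are constructed to share
    the same ink budget.
    """
    mats = gram_feature_matrix(dataset, backbone, layers, normalize)
    labels = dataset.labels
    return [
        probe_feature_matrix(
            mats.pop(l),
            labels,
            layer_id=l,
            feature_type="gram",
            color_mode="rgb",
            target_variance=target_variance,
            n_folds=n_folds,
            seed=seed,
            leakage_free=leakage_free,
        )
        for l in list(layers)
    ]


@dataclass
class GramScatter:
    """Two-PC projection of one layer's Gram vectors, for scatter plots."""

    scores: np.ndarray  # (n_images, n_components)
    explained_variance: np.ndarray
    ids: list[str]
    labels: np.ndarray
    layer_id: str


def gram_pca_scatter(
    dataset: LabeledDataset,
    backbone: Backbone,
    layer_id: str,
    n_components: int = 2,
    normalize=None,
) -> GramScatter:
    """Per-image scores on the first PCs of the layer's Gram vectors."""
    X = gram_feature_matrix(dataset, backbone, [layer_id], normalize)[layer_id]
    scores, evr = pca_scores_fixed(X, n_components)
    return GramScatter(
        scores=scores,
        explained_variance=evr,
        ids=dataset.ids,
        labels=dataset.labels,
        layer_id=layer_id,
    )
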