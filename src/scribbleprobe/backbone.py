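"""VGG19-style frozen feature extractor with per-layer activation access.

The backbone is the canonical 16-conv-layer VGG19 trunk (blocks of
2, 2, 4, 4, 4 convolutions with widths 64, 64, 128, 128, 256x4, 512x4,
512x4; all kernels 3x3 with padding 1; 2x2 max-pool after each block)
followed by the two hidden fully connected stages FC1 and FC2 of width
4096. The forward pass is implemented directly on numpy (im2col + BLAS
matmul, float32), since the backbone is never trained — it is only ever a
frozen feature extractor.

Weights come from one of two sources:

* ``"pretrained"`` — the published ImageNet weights. No weight file ships
  with this package and none can be downloaded in an offline run, so
  requesting this source raises :class:`WeightsUnavailableError`; the whole
  test-suite runs with seeded random weights instead.
* ``"seeded_random"`` — He-initialised random kernels with zero biases,
  reproducible from an integer seed. Random convolutional features are a
  standard, surprisingly strong baseline for linear probing, and they make
  every experiment runnable without any download.

Probed activations are post-ReLU (the standard convention; the choice is
documented here because it is a convention, not a derivation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data import IMAGE_SIZE, DrawingImage
from .stats import TTestResult, one_sample_ttest

#: Channel width of each of the 16 convolutional stages, in order.
CONV_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 256,
               512, 512, 512, 512, 512, 512, 512, 512)
#: 1-based conv indices after which a 2x2 max-pool is applied.
POOL_AFTER = frozenset({2, 4, 8, 12, 16})
FC_WIDTH = 4096

CONV_LAYERS = tuple(f"conv{i}" for i in range(1, 17))
FC_LAYERS = ("FC1", "FC2")
ALL_LAYERS = CONV_LAYERS + FC_LAYERS


class WeightsUnavailableError(RuntimeError):
    pass


def conv_spatial_size(i: int) -> int:
    """Spatial side length of the feature maps of conv layer ``i`` (1-based)."""
    n_pools = sum(1 for p in sorted(POOL_AFTER) if p < i)
    return IMAGE_SIZE // (2**n_pools)


def layer_shape(layer_id: str) -> tuple[int, ...]:
    """(C, H, W) for conv layers, (width,) for FC layers."""
    if layer_id in FC_LAYERS:
        return (FC_WIDTH,)
    if layer_id not in CONV_LAYERS:
        raise ValueError(f"unknown layer_id {layer_id!r}")
    i = int(layer_id[4:])
    s = conv_spatial_size(i)
    return (CONV_WIDTHS[i - 1], s, s)


def activation_length(layer_id: str) -> int:
    return int(np.prod(layer_shape(layer_id)))


def flatten_channel_major(act: np.ndarray) -> np.ndarray:
    """Flatten an (H, W, C) activation tensor as channel-major row-major maps.

    Each feature map is flattened row-major and the maps are concatenated
    in channel order, matching the activation-vector convention used by
    every probe in this package.
    """
    return np.ascontiguousarray(act.transpose(2, 0, 1)).reshape(-1)


@dataclass(frozen=True)
class ActivationVector:
    layer_id: str
    values: np.ndarray
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation vector contains non-finite values")


class Backbone:
    """Frozen feature extractor; weights are created lazily and cached.

    Each layer's weights are drawn from an independent child of
    ``SeedSequence([seed, layer_index])``, so the weights of any layer are
    identical no matter which subset of layers a caller touches first.
    """

    def __init__(self, weights_source: str = "seeded_random", seed: int = 0):
        if weights_source == "pretrained":
            raise WeightsUnavailableError(
                "No pretrained ImageNet weight file is bundled with this "
                "package and none can be fetched offline. Build the backbone "
                "with weights_source='seeded_random' (as the tests do), or "
                "load weights into Backbone._weights yourself."
            )
        if weights_source != "seeded_random":
            raise ValueError(
                "weights_source must be 'pretrained' or 'seeded_random'"
            )
        self.weights_source = weights_source
        self.seed = int(seed)
        self._weights: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- weights ---------------------------------------------------------
    @property
    def conv_layers(self) -> tuple[str, ...]:
        return CONV_LAYERS

    @property
    def fc_layers(self) -> tuple[str, ...]:
        return FC_LAYERS

    def _rng_for(self, layer_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, layer_index])
        )

    def conv_weights(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(W, b) of conv stage ``i`` (1-based); W has shape (9*Cin, Cout)."""
        key = f"conv{i}"
        if key not in self._weights:
            cin = 3 if i == 1 else CONV_WIDTHS[i - 2]
            cout = CONV_WIDTHS[i - 1]
            fan_in = 9 * cin
            rng = self._rng_for(i)
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(fan_in, cout)).astype(np.float32)
            b = np.zeros(cout, dtype=np.float32)
            self._weights[key] = (w, b)
        return self._weights[key]

    def fc_weights(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name not in FC_LAYERS:
            raise ValueError(f"unknown FC layer {name!r}")
        if name not in self._weights:
            # FC1 reads the flattened pool5 output (512 x 7 x 7)
            in_dim = CONV_WIDTHS[-1] * (conv_spatial_size(16) // 2) ** 2
            if name == "FC2":
                in_dim = FC_WIDTH
            rng = self._rng_for(17 if name == "FC1" else 18)
            w = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                           size=(in_dim, FC_WIDTH)).astype(np.float32)
            b = np.zeros(FC_WIDTH, dtype=np.float32)
            self._weights[name] = (w, b)
        return self._weights[name]

    # -- forward ---------------------------------------------------------
    @staticmethod
    def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        """3x3 same-padding convolution + ReLU on an (H, W, Cin) tensor."""
        h, wd, cin = x.shape
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(0, 1))  # (H, W, Cin, 3, 3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 4, 2)).reshape(
            h * wd, 9 * cin
        )
        out = cols @ w
        out += b
        np.maximum(out, 0.0, out=out)
        return out.reshape(h, wd, -1)

    @staticmethod
    def _maxpool2(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))

    def forward(
        self,
        pixels: np.ndarray,
        layers: Iterable[str] = ("conv16",),
    ) -> dict[str, np.ndarray]:
        """Run the forward pass, returning the requested post-ReLU tensors.

        Conv entries are (H, W, C) tensors; FC entries are 1-D vectors.
        Pixels are scaled to [0, 1]; no channel-mean subtraction is applied
        (with random weights there is no canonical preprocessing mean).
        """
        layers = set(layers)
        unknown = layers - set(ALL_LAYERS)
        if unknown:
            raise ValueError(f"unknown layer ids: {sorted(unknown)}")
        want_fc = bool(layers & set(FC_LAYERS))
        last_conv = max(
            (int(l[4:]) for l in layers if l.startswith("conv")), default=0
        )
        stop_at = 16 if want_fc else last_conv

        x = np.asarray(pixels, dtype=np.float32) / 255.0
        out: dict[str, np.ndarray] = {}
        for i in range(1, stop_at + 1):
            w, b = self.conv_weights(i)
            x = self._conv3x3(x, w, b)
            name = f"conv{i}"
            if name in layers:
                out[name] = x
            if i in POOL_AFTER and (i < stop_at or want_fc):
                x = self._maxpool2(x)
        if want_fc:
            flat = flatten_channel_major(x)  # pool5 output, 512*7*7
            w1, b1 = self.fc_weights("FC1")
            h1 = np.maximum(flat @ w1 + b1, 0.0)
            if "FC1" in layers:
                out["FC1"] = h1
            if "FC2" in layers:
                w2, b2 = self.fc_weights("FC2")
                out["FC2"] = np.maximum(h1 @ w2 + b2, 0.0)
        return out


def build_backbone(weights_source: str = "seeded_random", seed: int = 0) -> Backbone:
    """Construct the 16-conv-layer backbone with the requested weights."""
    return Backbone(weights_source=weights_source, seed=seed)


def extract_activation_vector(
    backbone: Backbone, image: DrawingImage, layer_id: str
) -> ActivationVector:
    """Flattened, channel-major activation vector of one image at one layer."""
    if layer_id not in ALL_LAYERS:
        raise ValueError(f"unknown layer_id {layer_id!r}")
    act = backbone.forward(image.pixels, layers=(layer_id,))[layer_id]
    values = act if act.ndim == 1 else flatten_channel_major(act)
    return ActivationVector(
        layer_id=layer_id, values=values, source_image_id=image.id
    )


def activation_matrix(
    backbone: Backbone,
    images: Sequence[DrawingImage],
    layer_ids: Sequence[str],
) -> dict[str, np.ndarray]:
    """One forward pass per image, collecting (n_images, L) matrices per layer."""
    mats: dict[str, list[np.ndarray]] = {l: [] for l in layer_ids}
    for im in images:
        acts = backbone.forward(im.pixels, layers=layer_ids)
        for l in layer_ids:
            a = acts[l]
            mats[l].append(a if a.ndim == 1 else flatten_channel_major(a))
    return {l: np.stack(v) for l, v in mats.items()}


@dataclass
class SubsampleReport:
    """Check that random 50% subsampling preserves the mean activation.

    For each of ``n_repeats`` repeats a fresh index set is drawn (without
    replacement, shared by every image) and the grand mean of the reduced
    activation matrix recorded; a one-sample t-test compares the repeat
    means to the grand mean of the original matrix. ``passed`` is True when
    the test is not significant at ``alpha``.
    """

    fraction: float
    n_repeats: int
    repeat_means: np.ndarray
    original_mean: float
    t_stat: float
    p_value: float
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return self.p_value > self.alpha


def subsample_activations(
    vectors: np.ndarray,
    fraction: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    n_repeats: int = 50,
    alpha: float = 0.05,
) -> tuple[np.ndarray, SubsampleReport]:
    """Reduce an (n_images, L) activation matrix by random column sampling.

    One index set per repeat, applied identically to every image (the
    probes' PCA needs feature correspondence across images). The returned
    matrix uses the first repeat's index set.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    vectors = np.atleast_2d(np.asarray(vectors))
    if rng is None:
        rng = np.random.default_rng(0)
    L = vectors.shape[1]
    k = int(round(fraction * L))
    col_means = vectors.mean(axis=0, dtype=np.float64)
    original_mean = float(col_means.mean())

    if fraction == 1.0:
        # identity reduction: every repeat reproduces the original mean exactly
        repeat_means = np.full(n_repeats, original_mean)
        reduced = vectors
    else:
        repeat_means = np.empty(n_repeats)
        reduced = None
        for r in range(n_repeats):
            idx = rng.permutation(L)[:k]
            repeat_means[r] = col_means[idx].mean()
            if r == 0:
                reduced = vectors[:, np.sort(idx)]

    if fraction == 1.0:
        t, p = 0.0, 1.0  # identity reduction: exact null by construction
    else:
        t, p, _ = one_sample_ttest(repeat_means, mu=original_mean)
    report = SubsampleReport(
        fraction=fraction,
        n_repeats=n_repeats,
        repeat_means=repeat_means,
        original_mean=original_mean,
        t_stat=t,
        p_value=p,
        alpha=alpha,
    )
    return reduced, report
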