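"""Input standardisation, NTSC grayscale, ink coverage, and train/val splitting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from sklearn.model_selection import train_test_split

from .data import IMAGE_SIZE, DrawingImage, LabeledDataset

#: NTSC luminance weights (Y = 0.299 R + 0.587 G + 0.114 B).
NTSC_WEIGHTS = (0.299, 0.587, 0.114)


def standardize(
    image,
    label: str = "unlabeled",
    image_id: str = "image",
    mode: str = "stretch",
) -> DrawingImage:
    """Resize any 3-channel raster to the network geometry (224, 224, 3).

    ``mode='stretch'`` resamples both axes independently (bilinear);
    ``mode='crop'`` first centre-crops to a square, then resizes.
    """
    if isinstance(image, Image.Image):
        arr = np.asarray(image)
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a 3-channel raster, got shape {arr.shape}")
    if arr.shape[:2] == (IMAGE_SIZE, IMAGE_SIZE):
        return DrawingImage(arr.astype(np.uint8), label=label, id=image_id)
    pil = Image.fromarray(arr.astype(np.uint8))
    if mode == "crop":
        w, h = pil.size
        s = min(w, h)
        left, top = (w - s) // 2, (h - s) // 2
        pil = pil.crop((left, top, left + s, top + s))
    elif mode != "stretch":
        raise ValueError("mode must be 'stretch' or 'crop'")
    pil = pil.resize((IMAGE_SIZE, IMAGE_SIZE), Image.BILINEAR)
    return DrawingImage(np.asarray(pil), label=label, id=image_id)


def to_grayscale_ntsc(image: DrawingImage) -> DrawingImage:
    """NTSC luminance, replicated to 3 channels.

    Y = 0.299 R + 0.587 G + 0.114 B, rounded half away from zero and
    clamped to [0, 255]. Idempotent up to +-1 grey level.
    """
    px = image.pixels.astype(np.float64)
    y = px[..., 0] * NTSC_WEIGHTS[0] + px[..., 1] * NTSC_WEIGHTS[1] + px[..., 2] * NTSC_WEIGHTS[2]
    y = np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)
    return DrawingImage(
        pixels=np.repeat(y[..., None], 3, axis=-1),
        label=image.label,
        id=image.id,
        color_mode="gray",
    )


def compute_coverage(
    image,
    background_color: Sequence[int] = (245, 245, 245),
    tolerance: float = 8.0,
) -> float:
    """Fraction of pixels whose max-channel distance from background exceeds ``tolerance``."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    px = image.pixels if isinstance(image, DrawingImage) else np.asarray(image)
    bg = np.asarray(background_color, dtype=np.int16)
    dist = np.abs(px.astype(np.int16) - bg).max(axis=-1)
    return float((dist > tolerance).mean())


def coverage_binarize(
    dataset: LabeledDataset,
    background_color: Sequence[int] = (245, 245, 245),
    tolerance: float = 8.0,
    labels: tuple[str, str] = ("low-coverage", "high-coverage"),
) -> LabeledDataset:
    """Relabel a dataset at its median ink coverage (balanced binary task).

    The split is by coverage rank (stable order), so the two classes differ
    in size by at most one image even when coverages tie at the median.
    """
    cov = np.array(
        [compute_coverage(im, background_color, tolerance) for im in dataset]
    )
    order = np.argsort(cov, kind="stable")
    half = len(dataset) // 2
    new_labels = np.empty(len(dataset), dtype=object)
    new_labels[order[:half]] = labels[0]
    new_labels[order[half:]] = labels[1]
    images = tuple(
        im.with_label(str(new_labels[i])) for i, im in enumerate(dataset)
    )
    return LabeledDataset(images, seed=dataset.seed)


@dataclass(frozen=True)
class SplitSpec:
    """Counts and policy for a train/validation partition."""

    train_count: int
    val_count: int
    stratified: bool = True
    seed: int = 0


def split_train_val(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition into train/val of exactly the requested sizes.

    Stratified mode preserves each class's share of the whole dataset in
    both sets to within one image. Deterministic given ``spec.seed``.
    """
    n = len(dataset)
    if spec.train_count + spec.val_count != n:
        raise ValueError(
            f"train_count + val_count = {spec.train_count + spec.val_count} "
            f"!= dataset size {n}"
        )
    indices = np.arange(n)
    if spec.stratified:
        tr, va = train_test_split(
            indices,
            test_size=spec.val_count,
            stratify=dataset.labels,
            random_state=spec.seed,
        )
    else:
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(n)
        tr, va = perm[: spec.train_count], perm[spec.train_count :]
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(va))
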