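"""Core containers: labelled 224x224 RGB drawings and ordered datasets.

Every stage of the pipeline operates on :class:`DrawingImage` objects whose
pixel block is exactly ``(224, 224, 3)`` uint8 — the input geometry of the
VGG19-family backbone. A :class:`LabeledDataset` is an ordered, reproducible
collection of such images together with the integer seed it was built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

IMAGE_SIZE = 224
COLOR_MODES = ("rgb", "gray")


@dataclass(frozen=True)
class DrawingImage:
    """A single 224x224x3 drawing with its class label and provenance id."""

    pixels: np.ndarray
    label: str
    id: str
    color_mode: str = "rgb"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(
                f"pixels must have shape (224, 224, 3), got {px.shape}"
            )
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.color_mode not in COLOR_MODES:
            raise ValueError(f"color_mode must be one of {COLOR_MODES}")
        if self.color_mode == "gray":
            if not (
                np.array_equal(px[..., 0], px[..., 1])
                and np.array_equal(px[..., 1], px[..., 2])
            ):
                raise ValueError("gray images must have three equal channels")

    def with_label(self, label: str) -> "DrawingImage":
        return replace(self, label=label)


@dataclass(frozen=True)
class LabeledDataset:
    """Ordered collection of drawings, reproducible from ``seed``."""

    images: tuple[DrawingImage, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "images", tuple(self.images))

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[DrawingImage]:
        return iter(self.images)

    def __getitem__(self, i: int) -> DrawingImage:
        return self.images[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images])

    @property
    def ids(self) -> list[str]:
        return [im.id for im in self.images]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for im in self.images:
            counts[im.label] = counts.get(im.label, 0) + 1
        return counts

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(tuple(self.images[i] for i in indices), seed=self.seed)

    def map_labels(self, grouping: Mapping[str, str]) -> "LabeledDataset":
        missing = sorted(set(l for l in self.labels) - set(grouping))
        if missing:
            raise KeyError(f"grouping does not cover labels: {missing}")
        return LabeledDataset(
            tuple(im.with_label(grouping[im.label]) for im in self.images),
            seed=self.seed,
        )


def save_dataset(
    dataset: LabeledDataset,
    directory: str | Path,
    preset: str = "",
) -> Path:
    """Write one PNG per image plus a ``manifest.csv`` and return its path.

    Manifest columns: id, filename, season, preset, seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in dataset.images:
        fname = f"{im.id}.png"
        Image.fromarray(im.pixels).save(directory / fname)
        rows.append(
            {
                "id": im.id,
                "filename": fname,
                "season": im.label,
                "preset": preset,
                "seed": dataset.seed,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> LabeledDataset:
    """Read a dataset back from a manifest written by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    directory = manifest_path.parent
    images = []
    for row in df.itertuples():
        px = np.asarray(Image.open(directory / row.filename).convert("RGB"))
        images.append(DrawingImage(pixels=px, label=str(row.season), id=str(row.id)))
    seed = int(df["seed"].iloc[0]) if len(df) else 0
    return LabeledDataset(tuple(images), seed=seed)
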