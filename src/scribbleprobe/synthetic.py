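"""Synthetic scribble generator with season-dependent colour, stroke and coverage statistics.

The original orangutan drawings are not publicly deposited, so this module
generates labelled stand-in scribbles whose four season classes can be made
to differ in (a) the crayon palette (green-dominant vs pink-dominant),
(b) stroke-shape statistics (count, width, curvature) and (c) ink coverage.
Strokes are constant-speed random walks with Gaussian turning angles, drawn
as hard-edged (no anti-aliasing) thick polylines over a near-white board,
so every pixel is either exactly a palette colour or exactly the
background — ink coverage is exactly countable.

All palette crayons share the same NTSC luminance (Y = 130 after rounding),
so presets that differ *only* in palette produce grayscale images that are
statistically identical across seasons: a grayscale probe on such data must
collapse to chance, which is the causal contract the probing experiments
rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .data import IMAGE_SIZE, DrawingImage, LabeledDataset

SEASONS = ("autumn", "spring", "summer", "winter")

#: Class counts of the study dataset (autumn, spring, summer, winter).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "autumn": 374,
    "spring": 269,
    "summer": 284,
    "winter": 372,
}

BACKGROUND = (245, 245, 245)

# Crayon colours, all with NTSC luminance 0.299R + 0.587G + 0.114B rounding
# to exactly 130, so palette-only class differences vanish in grayscale.
GREEN = (60, 180, 56)
PINK = (220, 78, 160)
BLUE = (80, 142, 200)
ORANGE = (200, 112, 40)
PURPLE = (150, 102, 220)
CRAYONS = (GREEN, PINK, BLUE, ORANGE, PURPLE)

PRESETS = ("paperlike", "null", "color-only", "shape-only", "style-only")

_STEP_LENGTH = 2.5  # px travelled per walk step
_STEPS_RANGE = (30, 90)  # walk steps per stroke
_MAX_STROKES_FOR_TARGET = 400  # cap when chasing a coverage_target


@dataclass(frozen=True)
class SeasonStyleParams:
    """Generative style of one season's scribbles.

    ``curvature_scale`` is the standard deviation (radians) of the Gaussian
    turning angle applied at each step of the random walk: 0 gives straight
    strokes, ~2 gives tight squiggles.
    """

    season_label: str
    palette: tuple[tuple[tuple[int, int, int], float], ...]
    stroke_count_range: tuple[int, int]
    stroke_width_range: tuple[int, int]
    curvature_scale: float
    coverage_target: Optional[float] = None
    background_color: tuple[int, int, int] = BACKGROUND

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.palette], dtype=float)
        if len(weights) == 0 or np.any(weights < 0):
            raise ValueError("palette weights must be non-negative and non-empty")
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("palette weights must sum to 1")
        for lo, hi in (self.stroke_count_range, self.stroke_width_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty (hi >= lo)")
        if self.curvature_scale < 0:
            raise ValueError("curvature_scale must be >= 0")
        if self.coverage_target is not None and not (
            0.0 <= self.coverage_target <= 1.0
        ):
            raise ValueError("coverage_target must lie in [0, 1]")


def _palette(dominant, dom_weight: float, secondary=None, sec_weight: float = 0.0):
    """Dominant crayon plus the rest of the box sharing the remainder."""
    rest = [c for c in CRAYONS if c != dominant and c != secondary]
    leftover = 1.0 - dom_weight - sec_weight
    out = [(dominant, dom_weight)]
    if secondary is not None:
        out.append((secondary, sec_weight))
    out += [(c, leftover / len(rest)) for c in rest]
    return tuple(out)


_UNIFORM_PALETTE = tuple((c, 1.0 / len(CRAYONS)) for c in CRAYONS)

# Season palettes: green dominates summer and winter, pink dominates spring
# and autumn; a distinct secondary crayon keeps all four pairwise different.
_SEASON_PALETTES = {
    "autumn": _palette(PINK, 0.65, ORANGE, 0.15),
    "spring": _palette(PINK, 0.65, BLUE, 0.15),
    "summer": _palette(GREEN, 0.65, BLUE, 0.15),
    "winter": _palette(GREEN, 0.65, PURPLE, 0.15),
}

# Shared stroke statistics for presets that must not vary shape by season.
_BASE_STROKES = dict(
    stroke_count_range=(8, 20), stroke_width_range=(3, 6), curvature_scale=0.35
)

# Per-season stroke statistics for presets that vary shape. The magnitudes
# are free parameters of the generator (no quantitative per-season stroke
# statistics exist for the real drawings); they are chosen to give visibly
# different but overlapping scribbles.
_SEASON_STROKES = {
    "autumn": dict(stroke_count_range=(6, 12), stroke_width_range=(6, 10),
                   curvature_scale=0.10),
    "spring": dict(stroke_count_range=(10, 18), stroke_width_range=(2, 4),
                   curvature_scale=0.45),
    "summer": dict(stroke_count_range=(18, 30), stroke_width_range=(2, 4),
                   curvature_scale=1.00),
    "winter": dict(stroke_count_range=(18, 30), stroke_width_range=(6, 10),
                   curvature_scale=2.00),
}

# Curvature-only variation: same palette, same counts, same widths, and low
# turning-angle spreads throughout, so strokes are locally straight for every
# season and the classes differ only in how much a stroke bends over tens to
# hundreds of pixels (direction decorrelates after ~1/sigma^2 steps). Small
# receptive fields cannot see that; large ones can.
_CURVATURE_ONLY = {
    "autumn": 0.03,
    "spring": 0.20,
    "summer": 0.80,
    "winter": 2.40,
}
# (kept geometric: each deeper receptive-field scale resolves one more pair)


def make_season_params(profile: str) -> dict[str, SeasonStyleParams]:
    """Return the per-season generative parameters of a named preset.

    Presets:

    * ``paperlike`` — seasons differ in palette AND stroke statistics
      (green-dominant summer/winter, pink-dominant spring/autumn).
    * ``color-only`` — only the (luminance-matched) palettes differ.
    * ``shape-only`` — only stroke count/width/curvature differ.
    * ``style-only`` — only stroke curvature differs (texture, not colour
      or ink budget).
    * ``null`` — all four seasons identical; downstream classifiers must
      not beat the dummy baseline.
    """
    if profile not in PRESETS:
        raise ValueError(f"unknown preset {profile!r}; known: {PRESETS}")
    params = {}
    for season in SEASONS:
        if profile == "paperlike":
            kw = dict(palette=_SEASON_PALETTES[season], **_SEASON_STROKES[season])
        elif profile == "color-only":
            kw = dict(palette=_SEASON_PALETTES[season], **_BASE_STROKES)
        elif profile == "shape-only":
            kw = dict(palette=_UNIFORM_PALETTE, **_SEASON_STROKES[season])
        elif profile == "style-only":
            # a shared coverage target pins the ink budget, so seasons differ
            # only in stroke layout (curvature), not in how much is drawn —
            # local statistics match, large-scale texture does not
            kw = dict(
                palette=_UNIFORM_PALETTE,
                stroke_count_range=(10, 16),
                stroke_width_range=(4, 6),
                curvature_scale=_CURVATURE_ONLY[season],
                coverage_target=0.30,
            )
        else:  # null
            kw = dict(palette=_UNIFORM_PALETTE, **_BASE_STROKES)
        params[season] = SeasonStyleParams(season_label=season, **kw)
    return params


def _brush_offsets(width: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dy, dx) offsets of a hard disk of the given stroke width."""
    r = width / 2.0
    ir = int(np.ceil(r))
    dy, dx = np.mgrid[-ir : ir + 1, -ir : ir + 1]
    mask = dy * dy + dx * dx <= r * r
    return dy[mask], dx[mask]


def _walk(rng: np.random.Generator, n_steps: int, curvature: float) -> np.ndarray:
    """Constant-speed random walk reflected at the canvas borders."""
    pos = np.empty((n_steps + 1, 2))
    pos[0] = rng.uniform(10, IMAGE_SIZE - 10, size=2)
    theta = rng.uniform(0, 2 * np.pi)
    for i in range(n_steps):
        theta += rng.normal(0.0, curvature)
        step = np.array([np.cos(theta), np.sin(theta)]) * _STEP_LENGTH
        nxt = pos[i] + step
        # reflect off borders by reversing the offending direction component
        for ax in (0, 1):
            if nxt[ax] < 0 or nxt[ax] > IMAGE_SIZE - 1:
                step[ax] = -step[ax]
                nxt = pos[i] + step
        theta = np.arctan2(step[1], step[0])
        pos[i + 1] = np.clip(nxt, 0, IMAGE_SIZE - 1)
    return pos


def _paint_stroke(
    canvas: np.ndarray,
    path: np.ndarray,
    width: int,
    color: tuple[int, int, int],
) -> None:
    # densify the polyline so the disk brush leaves no gaps
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    pts = [path[:1]]
    for i, L in enumerate(seg_len):
        n = max(int(np.ceil(L / 0.5)), 1)
        t = np.linspace(0, 1, n + 1)[1:, None]
        pts.append(path[i] + t * seg[i])
    dense = np.concatenate(pts, axis=0)
    cy = np.rint(dense[:, 0]).astype(np.intp)
    cx = np.rint(dense[:, 1]).astype(np.intp)
    dy, dx = _brush_offsets(width)
    yy = (cy[:, None] + dy[None, :]).ravel()
    xx = (cx[:, None] + dx[None, :]).ravel()
    ok = (yy >= 0) & (yy < IMAGE_SIZE) & (xx >= 0) & (xx < IMAGE_SIZE)
    canvas[yy[ok], xx[ok]] = color


def render_scribble(
    params: SeasonStyleParams,
    rng: np.random.Generator,
    image_id: str = "scribble",
) -> DrawingImage:
    """Draw one scribble; bit-deterministic given (params, generator state).

    Colour and width are sampled per stroke (crayon-like). If
    ``coverage_target`` is set, strokes are added until the inked fraction
    reaches the target (or a hard cap of 400 strokes).
    """
    canvas = np.empty((IMAGE_SIZE, IMAGE_SIZE, 3), dtype=np.uint8)
    canvas[:] = params.background_color

    colors = [c for c, _ in params.palette]
    weights = np.array([w for _, w in params.palette], dtype=float)
    weights = weights / weights.sum()

    lo, hi = params.stroke_count_range
    n_strokes = int(rng.integers(lo, hi + 1))
    if params.coverage_target is not None:
        n_strokes = _MAX_STROKES_FOR_TARGET

    bg = np.array(params.background_color, dtype=np.int16)
    total_px = IMAGE_SIZE * IMAGE_SIZE
    for _ in range(n_strokes):
        if params.coverage_target is not None:
            inked = np.any(canvas.astype(np.int16) != bg, axis=-1).sum()
            if inked / total_px >= params.coverage_target:
                break
        color = colors[int(rng.choice(len(colors), p=weights))]
        wlo, whi = params.stroke_width_range
        width = int(rng.integers(wlo, whi + 1))
        n_steps = int(rng.integers(_STEPS_RANGE[0], _STEPS_RANGE[1] + 1))
        path = _walk(rng, n_steps, params.curvature_scale)
        _paint_stroke(canvas, path, width, color)

    return DrawingImage(
        pixels=canvas, label=params.season_label, id=image_id, color_mode="rgb"
    )


def generate_dataset(
    params_by_season: Mapping[str, SeasonStyleParams],
    counts: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> LabeledDataset:
    """Generate ``counts[s]`` scribbles per season, reproducibly from ``seed``.

    Per-image generators are spawned from ``SeedSequence([seed, index])``
    where ``index`` is the image's global position, so any one image can be
    regenerated without the rest.
    """
    if counts is None:
        counts = DEFAULT_CLASS_COUNTS
    for season, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {season}: {n}")
    images = []
    index = 0
    for season in sorted(counts):
        params = params_by_season[season]
        for i in range(counts[season]):
            rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
            images.append(
                render_scribble(params, rng, image_id=f"{season}-{i:04d}")
            )
            index += 1
    return LabeledDataset(tuple(images), seed=seed)
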