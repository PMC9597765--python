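"""Synthetic scribble generator: presets, rendering, determinism, coverage."""

from dataclasses import asdict, replace

import numpy as np
import pytest

import scribbleprobe as sp
from scribbleprobe.synthetic import BACKGROUND, CRAYONS, SeasonStyleParams


def _dominant(palette):
    return max(palette, key=lambda cw: cw[1])[0]


class TestPresets:
    def test_paperlike_palette_dominance(self):
        """Green dominates summer/winter palettes; pink spring/autumn."""
        params = sp.make_season_params("paperlike")
        green, pink = CRAYONS[0], CRAYONS[1]
        assert _dominant(params["summer"].palette) == green
        assert _dominant(params["winter"].palette) == green
        assert _dominant(params["spring"].palette) == pink
        assert _dominant(params["autumn"].palette) == pink

    def test_null_identical_across_seasons(self):
        params = sp.make_season_params("null")
        ref = asdict(replace(params["autumn"], season_label="x"))
        for season in sp.SEASONS:
            assert asdict(replace(params[season], season_label="x")) == ref

    def test_color_only_strokes_identical_palettes_differ(self):
        params = sp.make_season_params("color-only")
        strokes = {
            (p.stroke_count_range, p.stroke_width_range, p.curvature_scale)
            for p in params.values()
        }
        assert len(strokes) == 1
        palettes = {tuple(p.palette) for p in params.values()}
        assert len(palettes) == 4

    def test_shape_only_palettes_identical_strokes_differ(self):
        params = sp.make_season_params("shape-only")
        assert len({tuple(p.palette) for p in params.values()}) == 1
        assert len({p.stroke_count_range for p in params.values()}) > 1

    def test_color_only_palettes_luminance_matched(self):
        """Every crayon of every palette maps to the same NTSC grey level."""
        params = sp.make_season_params("color-only")
        greys = set()
        for p in params.values():
            for (r, g, b), _ in p.palette:
                y = 0.299 * r + 0.587 * g + 0.114 * b
                greys.add(int(np.floor(y + 0.5)))
        assert len(greys) == 1

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            sp.make_season_params("watercolour")


class TestParamsValidation:
    def test_bad_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SeasonStyleParams("autumn", (((1, 2, 3), 0.4),), (1, 2), (1, 2), 0.1)

    def test_empty_interval(self):
        with pytest.raises(ValueError, match="non-empty"):
            SeasonStyleParams("autumn", (((1, 2, 3), 1.0),), (5, 2), (1, 2), 0.1)

    def test_coverage_target_range(self):
        with pytest.raises(ValueError, match="coverage_target"):
            SeasonStyleParams("autumn", (((1, 2, 3), 1.0),), (1, 2), (1, 2),
                              0.1, coverage_target=1.5)


class TestRender:
    def test_zero_strokes_gives_blank_background(self):
        params = replace(
            sp.make_season_params("null")["autumn"], stroke_count_range=(0, 0)
        )
        im = sp.render_scribble(params, np.random.default_rng(3))
        assert np.all(im.pixels == np.array(BACKGROUND, dtype=np.uint8))
        assert sp.compute_coverage(im) == 0.0

    def test_same_seed_bit_identical(self):
        params = sp.make_season_params("paperlike")["winter"]
        a = sp.render_scribble(params, np.random.default_rng(11))
        b = sp.render_scribble(params, np.random.default_rng(11))
        assert np.array_equal(a.pixels, b.pixels)

    def test_pixels_are_palette_or_background(self):
        """Hard-edged strokes: every pixel is exactly a crayon or the board."""
        params = sp.make_season_params("null")["summer"]
        im = sp.render_scribble(params, np.random.default_rng(5))
        colors = {c for c, _ in params.palette} | {BACKGROUND}
        seen = {tuple(px) for px in im.pixels.reshape(-1, 3)}
        assert seen <= colors

    def test_coverage_monotone_in_stroke_count(self):
        """More strokes never lowers mean ink coverage at fixed width."""
        base = sp.make_season_params("null")["autumn"]
        means = []
        for count in (1, 5, 20, 50):
            params = replace(base, stroke_count_range=(count, count),
                             stroke_width_range=(4, 4))
            covs = [
                sp.compute_coverage(
                    sp.render_scribble(params, np.random.default_rng(s))
                )
                for s in range(20)
            ]
            means.append(np.mean(covs))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_coverage_target_reached(self):
        params = replace(sp.make_season_params("null")["spring"],
                         coverage_target=0.2)
        im = sp.render_scribble(params, np.random.default_rng(0))
        assert sp.compute_coverage(im) >= 0.2


class TestGenerateDataset:
    def test_counts_and_ordering(self):
        params = sp.make_season_params("null")
        ds = sp.generate_dataset(params, {s: 2 for s in sp.SEASONS}, seed=9)
        assert len(ds) == 8
        assert ds.class_counts == {s: 2 for s in sp.SEASONS}

    def test_reproducible_from_seed(self):
        params = sp.make_season_params("paperlike")
        a = sp.generate_dataset(params, {s: 2 for s in sp.SEASONS}, seed=4)
        b = sp.generate_dataset(params, {s: 2 for s in sp.SEASONS}, seed=4)
        assert a.ids == b.ids
        for im_a, im_b in zip(a, b):
            assert np.array_equal(im_a.pixels, im_b.pixels)

    def test_different_seeds_differ(self):
        params = sp.make_season_params("paperlike")
        a = sp.generate_dataset(params, {"autumn": 1}, seed=4)
        b = sp.generate_dataset(params, {"autumn": 1}, seed=5)
        assert not np.array_equal(a[0].pixels, b[0].pixels)

    def test_negative_count(self):
        params = sp.make_season_params("null")
        with pytest.raises(ValueError, match="negative"):
            sp.generate_dataset(params, {"autumn": -1}, seed=0)


def test_save_and_load_round_trip(tmp_path):
    params = sp.make_season_params("paperlike")
    ds = sp.generate_dataset(params, {s: 1 for s in sp.SEASONS}, seed=2)
    manifest = sp.save_dataset(ds, tmp_path, preset="paperlike")
    loaded = sp.load_dataset(manifest)
    assert loaded.ids == ds.ids
    assert list(loaded.labels) == list(ds.labels)
    for a, b in zip(ds, loaded):
        assert np.array_equal(a.pixels, b.pixels)
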