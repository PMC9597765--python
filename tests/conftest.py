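"""Shared fixtures.

The expensive ingredients (backbone forwards, probe simulations, the tiny
end-to-end pipeline) are session-scoped so that module tests and the
acceptance suite measure the same computations instead of repeating them.
Simulation sizes are deliberately small (15-20 images per season) — the
probes' qualitative contracts hold at these sizes, see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import scribbleprobe as sp
from scribbleprobe.backbone import activation_matrix, subsample_activations
from scribbleprobe.content import make_svm, pca_reduce
from scribbleprobe.pipeline import RunConfig, run_full_study

N_PER_CLASS = 15
STYLE_N_PER_CLASS = 20
STYLE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def backbone():
    return sp.build_backbone("seeded_random", seed=0)


@pytest.fixture(scope="session")
def paperlike_small():
    params = sp.make_season_params("paperlike")
    return sp.generate_dataset(
        params, {s: N_PER_CLASS for s in sp.SEASONS}, seed=0
    )


@pytest.fixture(scope="session")
def paperlike_activations(backbone, paperlike_small):
    """conv1/conv8/conv16 activation matrices of the paperlike dataset.

    conv1 is 50%-subsampled (shared index sets) with its t-test report,
    exactly as the probes consume it.
    """
    mats = activation_matrix(
        backbone, list(paperlike_small), ["conv1", "conv8", "conv16"]
    )
    rng = np.random.default_rng(0)
    reduced, report = subsample_activations(mats["conv1"], 0.5, rng)
    return {
        "conv1": reduced,
        "conv1_report": report,
        "conv1_full_width": mats["conv1"].shape[1],
        "conv8": mats["conv8"],
        "conv16": mats["conv16"],
        "labels": paperlike_small.labels,
    }


def pooled_from_conv16_rows(rows: np.ndarray) -> np.ndarray:
    """Global average pooling recovered from flattened conv16 vectors."""
    n = rows.shape[0]
    return rows.reshape(n, 512, -1).mean(axis=2)


@pytest.fixture(scope="session")
def null_small(backbone):
    params = sp.make_season_params("null")
    ds = sp.generate_dataset(params, {s: N_PER_CLASS for s in sp.SEASONS}, seed=0)
    mats = activation_matrix(backbone, list(ds), ["conv1", "conv16"])
    return {"dataset": ds, "conv1": mats["conv1"], "conv16": mats["conv16"]}


@pytest.fixture(scope="session")
def color_only_probes(backbone):
    """conv1 probe accuracies for the color-only preset, RGB vs grayscale.

    Three dataset seeds; the grayscale probe must collapse to chance
    because every crayon shares the same NTSC luminance.
    """
    params = sp.make_season_params("color-only")
    out = {"rgb": [], "gray": [], "dummy": []}
    for seed in (0, 1, 2):
        ds = sp.generate_dataset(params, {s: N_PER_CLASS for s in sp.SEASONS},
                                 seed=seed)
        out["dummy"].append(sp.dummy_accuracy(ds.labels))
        for mode in ("rgb", "gray"):
            res = sp.probe_layers(ds, backbone, layers=["conv1"],
                                  color_mode=mode, n_folds=5, seed=seed)
            out[mode].append(res[0].mean_accuracy)
    return out


@pytest.fixture(scope="session")
def null_probes(backbone, null_small):
    """conv1 activation-probe accuracies on three null-preset datasets."""
    from scribbleprobe.content import probe_feature_matrix

    accs = []
    # seed 0 reuses the cached forward pass
    X, _ = subsample_activations(null_small["conv1"], 0.5,
                                 np.random.default_rng(0))
    r = probe_feature_matrix(X, null_small["dataset"].labels,
                             "conv1", "activation", "rgb", n_folds=5, seed=0)
    accs.append(r.mean_accuracy)
    params = sp.make_season_params("null")
    for seed in (1, 2):
        ds = sp.generate_dataset(params, {s: N_PER_CLASS for s in sp.SEASONS},
                                 seed=seed)
        res = sp.probe_layers(ds, backbone, layers=["conv1"], n_folds=5,
                              seed=seed)
        accs.append(res[0].mean_accuracy)
    return accs


@pytest.fixture(scope="session")
def style_slope(backbone):
    """Pooled accuracy-vs-depth regression of the style-only gram probe.

    Three dataset seeds, all 16 conv layers, unit-normalised Gram vectors
    (the preset pins the ink budget, so the energy-free co-activation
    structure carries the style signal).
    """
    layers = [f"conv{i}" for i in range(1, 17)]
    params = sp.make_season_params("style-only")
    depths, accs, profiles = [], [], []
    for seed in STYLE_SEEDS:
        ds = sp.generate_dataset(
            params, {s: STYLE_N_PER_CLASS for s in sp.SEASONS}, seed=seed
        )
        res = sp.gram_probe_layers(ds, backbone, layers=layers, seed=seed,
                                   normalize="unit")
        profiles.append([r.mean_accuracy for r in res])
        depths.extend(range(1, 17))
        accs.extend(profiles[-1])
    test = sp.slope_test(accs, depths=depths)
    return {"test": test, "profiles": profiles}


@pytest.fixture(scope="session")
def head_runs(backbone, paperlike_small, paperlike_activations, null_small):
    """Transfer-head val accuracies on paperlike vs null synthetic data.

    Pooled conv16 features are recovered from the cached activation rows;
    patience is scaled (15 epochs) so the tolerated number of SGD steps
    matches the study's protocol at its ~30x larger sample size.
    """
    results = {}
    for name, ds, rows in (
        ("paperlike", paperlike_small, paperlike_activations["conv16"]),
        ("null", null_small["dataset"], null_small["conv16"]),
    ):
        pooled = pooled_from_conv16_rows(rows)
        cache = {(im.id, False): pooled[i] for i, im in enumerate(ds)}
        tr, va = sp.split_train_val(ds, sp.SplitSpec(40, 20, seed=0))
        accs = []
        for seed in (0, 1, 2):
            cfg = sp.HeadConfig(n_classes=4, seed=seed, augment=False,
                                max_epochs=80, patience_epochs=15)
            model, hist = sp.train_head(backbone, tr, va, cfg,
                                        feature_cache=cache)
            acc, _ = sp.evaluate(model, va)
            accs.append(acc)
        results[name] = {"val_accuracies": accs,
                         "dummy": sp.dummy_accuracy(va.labels),
                         "history": hist}
    return results


@pytest.fixture(scope="session")
def type_one_error_rate():
    """Rejection rate of the 5x2cv test under a true null (200 runs).

    Two logistic regressions read two exchangeable (identically
    distributed, equally informative) features of the same Gaussian
    two-class data, so they have equal expected accuracy by symmetry.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import FunctionTransformer

    def column_model(j):
        return make_pipeline(
            FunctionTransformer(lambda X, j=j: X[:, [j]]),
            LogisticRegression(),
        )

    n_runs, rejections = 200, 0
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([42, run]))
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 2)) + 0.8 * y[:, None]
        res = sp.paired_5x2cv_ttest(column_model(0), column_model(1), X, y,
                                    seed=run)
        if res.p_value < 0.05:
            rejections += 1
    return rejections / n_runs


TINY_CONFIG = dict(
    preset="paperlike",
    counts={s: 4 for s in sp.SEASONS},
    val_fraction=0.25,
    probe_layer_ids=("conv1", "conv8", "conv16"),
    color_modes=("rgb",),
    n_folds=4,
    augment=False,
    max_epochs=3,
    patience_epochs=2,
    binary_tasks=True,
)


@pytest.fixture(scope="session")
def tiny_pipeline_pair(tmp_path_factory):
    """The same tiny study run twice into fresh directories."""
    dirs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"study_{tag}")
        cfg = RunConfig(**TINY_CONFIG, out_dir=str(out))
        run_full_study(cfg)
        dirs.append(out)
    return dirs
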