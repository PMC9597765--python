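"""End-to-end study orchestration: simulate -> prep -> train -> probe -> stats -> report.

Each stage writes its outputs under ``<out_dir>/<stage>/`` together with a
``.stage_key`` fingerprint (a hash of the stage-relevant configuration and
of every upstream fingerprint). Re-running a study resumes from the first
stage whose fingerprint changed, so changing e.g. the dataset seed
invalidates everything downstream while editing only the probe layer list
re-uses the simulated images.

Every figure the report emits has a CSV twin holding exactly the numbers
plotted.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .backbone import Backbone, build_backbone
from .content import DEPTH_INDEX, make_svm, pca_reduce, probe_layers, slope_test
from .data import LabeledDataset, load_dataset, save_dataset
from .head import ConfusionMatrix, HeadConfig, evaluate, relabel, train_head
from .prep import SplitSpec, compute_coverage, coverage_binarize, split_train_val
from .stats import comparison_table, dummy_accuracy, paired_5x2cv_ttest, ttest_5x2cv_from_accuracies
from .style import gram_pca_scatter, gram_probe_layers
from .synthetic import DEFAULT_CLASS_COUNTS, generate_dataset, make_season_params

from sklearn.dummy import DummyClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully-seeded description of one study run.

    Unknown keys in a config file are errors — a silently ignored typo in,
    say, ``dataset_seed`` would corrupt any reproducibility claim.
    """

    preset: str = "paperlike"
    counts: Optional[dict] = None  # None -> the study's 374/269/284/372
    val_fraction: float = 0.3
    weights_source: str = "seeded_random"
    weights_seed: int = 0
    probe_layer_ids: tuple = ("conv1", "conv2", "conv4", "conv8", "conv12", "conv16")
    color_modes: tuple = ("rgb", "gray")
    n_folds: int = 10
    target_variance: float = 0.8
    augment: bool = True
    max_epochs: int = 50
    patience_epochs: int = 3
    binary_tasks: bool = True
    dataset_seed: int = 0
    split_seed: int = 1
    train_seed: int = 2
    fold_seed: int = 3
    out_dir: str = "study-out"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["probe_layer_ids"] = list(self.probe_layer_ids)
        d["color_modes"] = list(self.color_modes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("probe_layer_ids", "color_modes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# stage plumbing


def _key(payload: dict, *upstream: str) -> str:
    blob = json.dumps({"payload": payload, "upstream": list(upstream)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage_dir(out: Path, name: str) -> Path:
    d = out / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _fresh(stage: Path, key: str) -> bool:
    f = stage / ".stage_key"
    return f.exists() and f.read_text() == key


def _mark(stage: Path, key: str) -> None:
    (stage / ".stage_key").write_text(key)


def _log(stage: str, key: str, t0: float) -> None:
    print(
        json.dumps(
            {"stage": stage, "key": key[:12], "seconds": round(time.time() - t0, 2)}
        )
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, out: Path) -> str:
    stage = _stage_dir(out, "simulate")
    counts = dict(config.counts) if config.counts else dict(DEFAULT_CLASS_COUNTS)
    key = _key({"preset": config.preset, "counts": counts,
                "seed": config.dataset_seed})
    if _fresh(stage, key):
        return key
    t0 = time.time()
    params = make_season_params(config.preset)
    dataset = generate_dataset(params, counts, seed=config.dataset_seed)
    save_dataset(dataset, stage, preset=config.preset)
    _mark(stage, key)
    _log("simulate", key, t0)
    return key


def _load_simulated(out: Path) -> LabeledDataset:
    return load_dataset(out / "simulate" / "manifest.csv")


def stage_prep(config: RunConfig, out: Path, sim_key: str) -> str:
    stage = _stage_dir(out, "prep")
    key = _key({"val_fraction": config.val_fraction, "seed": config.split_seed},
               sim_key)
    if _fresh(stage, key):
        return key
    t0 = time.time()
    dataset = _load_simulated(out)
    n = len(dataset)
    val_count = int(round(config.val_fraction * n))
    spec = SplitSpec(train_count=n - val_count, val_count=val_count,
                     stratified=True, seed=config.split_seed)
    train, val = split_train_val(dataset, spec)
    rows = []
    members = {im.id: "train" for im in train}
    members.update({im.id: "val" for im in val})
    for im in dataset:
        rows.append(
            {"id": im.id, "filename": f"{im.id}.png", "label": im.label,
             "subset": members[im.id],
             "coverage": compute_coverage(im)}
        )
    _write_csv(pd.DataFrame(rows), stage / "split.csv")
    _mark(stage, key)
    _log("prep", key, t0)
    return key


def _load_split(config: RunConfig, out: Path) -> tuple[LabeledDataset, LabeledDataset]:
    dataset = _load_simulated(out)
    df = pd.read_csv(out / "prep" / "split.csv")
    subset = dict(zip(df["id"].astype(str), df["subset"]))
    tr = [i for i, im in enumerate(dataset) if subset[im.id] == "train"]
    va = [i for i, im in enumerate(dataset) if subset[im.id] == "val"]
    return dataset.subset(tr), dataset.subset(va)


def _train_task(backbone, train, val, config: RunConfig, n_classes: int):
    head_cfg = HeadConfig(
        n_classes=n_classes,
        seed=config.train_seed,
        augment=config.augment,
        max_epochs=config.max_epochs,
        patience_epochs=config.patience_epochs,
    )
    model, history = train_head(backbone, train, val, head_cfg)
    acc, cm = evaluate(model, val)
    return model, history, acc, cm


def stage_train(config: RunConfig, out: Path, prep_key: str) -> str:
    stage = _stage_dir(out, "train")
    key = _key(
        {"weights": [config.weights_source, config.weights_seed],
         "train_seed": config.train_seed, "augment": config.augment,
         "max_epochs": config.max_epochs, "patience": config.patience_epochs,
         "binary": config.binary_tasks},
        prep_key,
    )
    if _fresh(stage, key):
        return key
    t0 = time.time()
    backbone = build_backbone(config.weights_source, config.weights_seed)
    train, val = _load_split(config, out)
    metrics = {}

    def run_task(name: str, tr: LabeledDataset, va: LabeledDataset) -> None:
        n_classes = len(set(tr.labels))
        model, history, acc, cm = _train_task(backbone, tr, va, config, n_classes)
        _write_csv(history, stage / f"history_{name}.csv")
        cm.to_frame().to_csv(stage / f"confusion_{name}.csv", float_format="%.10g")
        metrics[name] = {
            "val_accuracy": acc,
            "dummy_accuracy": dummy_accuracy(va.labels),
            "best_epoch": int(history.attrs["best_epoch"]),
            "classes": list(model.classes),
        }

    run_task("seasons", train, val)
    if config.binary_tasks:
        cold_warm = {"autumn": "cold", "winter": "cold",
                     "spring": "warm", "summer": "warm"}
        run_task("cold_warm", relabel(train, cold_warm), relabel(val, cold_warm))
        dataset = _load_simulated(out)
        cov = coverage_binarize(dataset)
        cov_by_id = {im.id: im.label for im in cov}
        run_task(
            "coverage",
            LabeledDataset(tuple(im.with_label(cov_by_id[im.id]) for im in train),
                           seed=train.seed),
            LabeledDataset(tuple(im.with_label(cov_by_id[im.id]) for im in val),
                           seed=val.seed),
        )
    (stage / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _mark(stage, key)
    _log("train", key, t0)
    return key


def _probe_tidy(results, extra: dict) -> pd.DataFrame:
    rows = []
    for r in results:
        for fold, acc in enumerate(r.fold_accuracies):
            rows.append(
                {"layer_id": r.layer_id, "depth_index": DEPTH_INDEX[r.layer_id],
                 "feature_type": r.feature_type, "color_mode": r.color_mode,
                 "fold": fold, "accuracy": acc, **extra}
            )
    return pd.DataFrame(rows)


def stage_probe_content(config: RunConfig, out: Path, prep_key: str) -> str:
    stage = _stage_dir(out, "probe_content")
    key = _key(
        {"layers": list(config.probe_layer_ids), "modes": list(config.color_modes),
         "folds": config.n_folds, "tv": config.target_variance,
         "weights": [config.weights_source, config.weights_seed],
         "fold_seed": config.fold_seed},
        prep_key,
    )
    if _fresh(stage, key):
        return key
    t0 = time.time()
    backbone = build_backbone(config.weights_source, config.weights_seed)
    dataset = _load_simulated(out)
    frames, summary = [], {}
    for mode in config.color_modes:
        results = probe_layers(
            dataset, backbone, layers=config.probe_layer_ids, color_mode=mode,
            target_variance=config.target_variance, n_folds=config.n_folds,
            seed=config.fold_seed,
        )
        frames.append(_probe_tidy(results, {}))
        st = slope_test(results)
        summary[mode] = {
            "layers": {
                r.layer_id: {"mean": r.mean_accuracy, "sd": r.sd_accuracy,
                             "n_components": r.n_components_retained}
                for r in results
            },
            "slope": st.slope, "slope_p": st.p_value,
            "subsample_checks": {
                r.layer_id: {"t": r.subsample_report.t_stat,
                             "p": r.subsample_report.p_value,
                             "passed": r.subsample_report.passed}
                for r in results if r.subsample_report is not None
            },
        }
    _write_csv(pd.concat(frames, ignore_index=True), stage / "content_probe.csv")
    (stage / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _mark(stage, key)
    _log("probe-content", key, t0)
    return key


def stage_probe_style(config: RunConfig, out: Path, prep_key: str) -> str:
    stage = _stage_dir(out, "probe_style")
    conv_layers = [l for l in config.probe_layer_ids if l.startswith("conv")]
    key = _key(
        {"layers": conv_layers, "folds": config.n_folds,
         "tv": config.target_variance,
         "weights": [config.weights_source, config.weights_seed],
         "fold_seed": config.fold_seed},
        prep_key,
    )
    if _fresh(stage, key):
        return key
    t0 = time.time()
    backbone = build_backbone(config.weights_source, config.weights_seed)
    dataset = _load_simulated(out)
    results = gram_probe_layers(
        dataset, backbone, layers=conv_layers, n_folds=config.n_folds,
        target_variance=config.target_variance, seed=config.fold_seed,
    )
    _write_csv(_probe_tidy(results, {}), stage / "style_probe.csv")
    st = slope_test(results)
    summary = {
        "layers": {r.layer_id: {"mean": r.mean_accuracy, "sd": r.sd_accuracy,
                                "n_components": r.n_components_retained}
                   for r in results},
        "slope": st.slope, "slope_p": st.p_value,
    }
    (stage / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    # two-PC scatters of the two earliest probed conv layers
    scatter_frames = []
    for layer in conv_layers[:2]:
        sc = gram_pca_scatter(dataset, backbone, layer)
        df = pd.DataFrame(
            {"id": sc.ids, "PC1": sc.scores[:, 0], "PC2": sc.scores[:, 1],
             "season": sc.labels, "layer_id": layer}
        )
        scatter_frames.append(df)
    _write_csv(pd.concat(scatter_frames, ignore_index=True),
               stage / "gram_scatter.csv")
    _mark(stage, key)
    _log("probe-style", key, t0)
    return key


def stage_stats(config: RunConfig, out: Path, content_key: str,
                style_key: str) -> str:
    """5x2cv comparisons per layer: rgb vs dummy, gray vs dummy, rgb vs gray."""
    stage = _stage_dir(out, "stats")
    key = _key({"fold_seed": config.fold_seed}, content_key, style_key)
    if _fresh(stage, key):
        return key
    t0 = time.time()
    backbone = build_backbone(config.weights_source, config.weights_seed)
    dataset = _load_simulated(out)
    y = dataset.labels
    rows = []
    score_cache: dict[tuple, np.ndarray] = {}

    from .backbone import activation_matrix, subsample_activations
    from .prep import to_grayscale_ntsc
    from .style import gram_feature_matrix

    def scores_for(mode: str, layer: str) -> np.ndarray:
        ck = (mode, layer)
        if ck not in score_cache:
            imgs = list(dataset)
            if mode == "gray":
                imgs = [to_grayscale_ntsc(im) for im in imgs]
            X = activation_matrix(backbone, imgs, [layer])[layer]
            if layer in ("conv1", "conv2"):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.fold_seed, DEPTH_INDEX[layer]])
                )
                X, _ = subsample_activations(X, 0.5, rng)
            score_cache[ck] = pca_reduce(X, config.target_variance).scores
        return score_cache[ck]

    dummy = DummyClassifier(strategy="most_frequent")
    for layer in config.probe_layer_ids:
        for mode in config.color_modes:
            res = paired_5x2cv_ttest(
                make_svm(seed=config.fold_seed), dummy,
                scores_for(mode, layer), y, seed=config.fold_seed,
            )
            rows.append({"comparison": f"{mode}-vs-dummy", "layer": layer,
                         "t": res.t_statistic, "p": res.p_value,
                         "degenerate": res.degenerate})
        if set(config.color_modes) >= {"rgb", "gray"}:
            accs_a = np.empty((5, 2))
            accs_b = np.empty((5, 2))
            Xa, Xb = scores_for("rgb", layer), scores_for("gray", layer)
            for r in range(5):
                rs = int(np.random.SeedSequence(
                    [config.fold_seed, r]).generate_state(1)[0] % 2**31)
                skf = StratifiedKFold(2, shuffle=True, random_state=rs)
                for f, (tr, te) in enumerate(skf.split(Xa, y)):
                    for accs, X in ((accs_a, Xa), (accs_b, Xb)):
                        m = make_svm(seed=config.fold_seed)
                        m.fit(X[tr], y[tr])
                        accs[r, f] = float(np.mean(m.predict(X[te]) == y[te]))
            t, p, degen = ttest_5x2cv_from_accuracies(accs_a, accs_b)
            rows.append({"comparison": "rgb-vs-gray", "layer": layer,
                         "t": t, "p": p, "degenerate": degen})
    df = comparison_table(rows)
    _write_csv(df, stage / "comparisons.csv")
    _mark(stage, key)
    _log("stats", key, t0)
    return key


def stage_report(config: RunConfig, out: Path, *upstream: str) -> str:
    stage = _stage_dir(out, "report")
    key = _key({"version": __version__}, *upstream)
    if _fresh(stage, key):
        return key
    t0 = time.time()

    # confusion heat map
    cm = pd.read_csv(out / "train" / "confusion_seasons.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(cm.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(cm.columns)), cm.columns, rotation=45)
    ax.set_yticks(range(len(cm.index)), cm.index)
    for i in range(len(cm.index)):
        for j in range(len(cm.columns)):
            ax.text(j, i, int(cm.iloc[i, j]), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(stage / "confusion_seasons.png", dpi=120)
    plt.close(fig)
    cm.to_csv(stage / "confusion_seasons.csv", float_format="%.10g")

    # layer accuracy curves (content rgb/gray + gram)
    content = pd.read_csv(out / "probe_content" / "content_probe.csv")
    style = pd.read_csv(out / "probe_style" / "style_probe.csv")
    both = pd.concat([content, style], ignore_index=True)
    curves = (
        both.groupby(["feature_type", "color_mode", "layer_id", "depth_index"])
        ["accuracy"].agg(["mean", "std"]).reset_index()
        .sort_values(["feature_type", "color_mode", "depth_index"])
    )
    _write_csv(curves, stage / "layer_accuracy_curves.csv")

    fig, ax = plt.subplots(figsize=(6.5, 4))
    for (ftype, mode), grp in curves.groupby(["feature_type", "color_mode"]):
        ax.errorbar(grp["depth_index"], grp["mean"], yerr=grp["std"],
                    marker="o", capsize=3, label=f"{ftype} ({mode})")
    ax.set_xlabel("layer depth index")
    ax.set_ylabel("10-fold CV accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(stage / "layer_accuracy_curves.png", dpi=120)
    plt.close(fig)

    # gram scatter
    scat = pd.read_csv(out / "probe_style" / "gram_scatter.csv")
    layers = scat["layer_id"].unique()
    fig, axes = plt.subplots(1, len(layers), figsize=(5 * len(layers), 4),
                             squeeze=False)
    for ax, layer in zip(axes[0], layers):
        sub = scat[scat["layer_id"] == layer]
        for season, grp in sub.groupby("season"):
            ax.scatter(grp["PC1"], grp["PC2"], s=12, label=season, alpha=0.7)
        ax.set_title(layer)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(stage / "gram_scatter.png", dpi=120)
    plt.close(fig)
    _write_csv(scat, stage / "gram_scatter.csv")

    manifest = {
        "version": __version__,
        "config": {**asdict(config),
                   "probe_layer_ids": list(config.probe_layer_ids),
                   "color_modes": list(config.color_modes)},
        "stage_keys": {f"stage_{i}": k for i, k in enumerate(upstream)},
    }
    (stage / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    _mark(stage, key)
    _log("report", key, t0)
    return key


def run_full_study(config: RunConfig) -> dict[str, Path]:
    """Run every stage (resuming from caches) and return output locations."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = stage_simulate(config, out)
    prep = stage_prep(config, out, sim)
    train = stage_train(config, out, prep)
    content = stage_probe_content(config, out, prep)
    style = stage_probe_style(config, out, prep)
    stats = stage_stats(config, out, content, style)
    report = stage_report(config, out, sim, prep, train, content, style, stats)
    return {name: out / name for name in
            ("simulate", "prep", "train", "probe_content", "probe_style",
             "stats", "report")}
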