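"""Layer-wise content probing: PCA to 80% variance + linear-SVM 10-fold CV.

For each probed layer the activation vectors of every image are stacked
into an (n_images, L) matrix, reduced by PCA to the smallest number of
principal components explaining at least 80% of the variance, and the PC
scores are classified by a linear SVM under stratified 10-fold
cross-validation. The early layers conv1 and conv2 are first reduced to
50% of their activations by shared random subsampling (their activation
vectors are in the millions), with a t-test report certifying that the
subsampling preserved the mean activation.

PCA is computed through the dual (Gram) eigendecomposition: with far more
features than images, the n x n matrix ``Xc Xc^T`` carries the whole
spectrum at a fraction of the memory of an SVD of ``Xc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .backbone import ALL_LAYERS, CONV_LAYERS, FC_LAYERS, Backbone, activation_matrix, subsample_activations, SubsampleReport
from .data import LabeledDataset
from .prep import to_grayscale_ntsc

#: Depth index used for accuracy-vs-depth regressions: conv1..conv16 -> 1..16,
#: FC1 -> 17, FC2 -> 18.
DEPTH_INDEX = {**{f"conv{i}": i for i in range(1, 17)}, "FC1": 17, "FC2": 18}


@dataclass
class PCAReduction:
    scores: np.ndarray
    n_components: int
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    _basis: Optional[np.ndarray] = None  # (n, k) left singular vectors / sing. values
    _X_centered: Optional[np.ndarray] = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows onto the retained components (for leakage-free CV)."""
        if self._basis is None or self._X_centered is None:
            raise RuntimeError("projection basis not retained")
        # components^T = Xc^T U S^{-1}; scores_new = (X - mean) @ components^T
        return (np.asarray(X) - self.mean) @ (self._X_centered.T @ self._basis)


def _pca_spectrum(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-spectrum of the centred data via the dual n x n problem."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must contain only finite values")
    mean = X.mean(axis=0)
    Xc = X - mean
    if Xc.size <= 5_000_000:
        Xc = Xc.astype(np.float64)
    K = (Xc @ Xc.T).astype(np.float64)
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0 or not np.any(evals > 0):
        raise ValueError("matrix has zero variance (constant rows)")
    return mean, Xc, evals, evecs


def pca_reduce(
    X: np.ndarray,
    target_variance: float = 0.80,
    keep_basis: bool = False,
) -> PCAReduction:
    """Project onto the minimal set of PCs explaining ``target_variance``.

    ``n_components`` is the smallest k whose cumulative explained-variance
    ratio reaches the target; a constant matrix raises ``ValueError``.
    """
    if not (0.0 < target_variance <= 1.0):
        raise ValueError("target_variance must lie in (0, 1]")
    mean, Xc, evals, evecs = _pca_spectrum(X)
    ratios = evals / evals.sum()
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, target_variance - 1e-12) + 1)
    k = min(k, int(np.sum(evals > evals[0] * 1e-12)))  # never exceed rank
    # scores = U_k * sqrt(eigvals_k); equals Xc projected on the components
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    basis = evecs[:, :k] / np.sqrt(evals[:k]) if keep_basis else None
    return PCAReduction(
        scores=scores,
        n_components=k,
        explained_variance_ratio=ratios,
        mean=mean,
        _basis=basis,
        _X_centered=Xc if keep_basis else None,
    )


def pca_scores_fixed(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores and explained-variance ratios for a fixed component count."""
    _, _, evals, evecs = _pca_spectrum(X)
    ratios = evals / evals.sum()
    k = min(n_components, evecs.shape[1])
    return evecs[:, :k] * np.sqrt(evals[:k]), ratios[:k]


def make_svm(C: float = 1.0, seed: int = 0):
    """Standardise-then-linear-SVM pipeline (one-vs-rest, cost C)."""
    return make_pipeline(
        StandardScaler(),
        LinearSVC(C=C, random_state=seed, max_iter=10_000),
    )


def svm_cv_accuracy(
    features: np.ndarray,
    labels: Sequence,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Per-fold accuracies of the linear SVM under (stratified) k-fold CV.

    Every sample is evaluated exactly once. When ``n_folds`` equals the
    sample count the CV degenerates to leave-one-out (unstratified by
    necessity); otherwise folds are stratified and every class must have at
    least ``n_folds`` members.
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    n = len(y)
    if n_folds == n:
        splitter = KFold(n_splits=n)  # leave-one-out
    else:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} members < n_folds="
                f"{n_folds}; lower n_folds"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in splitter.split(X, y):
        model = make_svm(C=C, seed=seed)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return np.array(accs)


@dataclass
class LayerProbeResult:
    """CV accuracy of one layer's probe under a stated feature type."""

    layer_id: str
    feature_type: str  # "activation" | "gram"
    color_mode: str  # "rgb" | "gray"
    fold_accuracies: np.ndarray
    n_components_retained: int
    subsample_report: Optional[SubsampleReport] = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def depth_index(self) -> int:
        return DEPTH_INDEX[self.layer_id]


def probe_feature_matrix(
    X: np.ndarray,
    labels: Sequence,
    layer_id: str,
    feature_type: str,
    color_mode: str,
    target_variance: float = 0.80,
    n_folds: int = 10,
    seed: int = 0,
    leakage_free: bool = False,
    subsample_report: Optional[SubsampleReport] = None,
) -> LayerProbeResult:
    """PCA + SVM CV on a ready-made (n_images, L) feature matrix.

    Default behaviour fits PCA on all images before cross-validating the
    SVM (the study's protocol); ``leakage_free=True`` refits the PCA inside
    each training fold instead.
    """
    y = np.asarray(labels)
    if leakage_free:
        _, counts = np.unique(y, return_counts=True)
        if n_folds != len(y) and counts.min() < n_folds:
            raise ValueError("smallest class too small for n_folds")
        splitter = (
            KFold(n_splits=n_folds)
            if n_folds == len(y)
            else StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        )
        accs, ks = [], []
        for tr, te in splitter.split(X, y):
            red = pca_reduce(X[tr], target_variance, keep_basis=True)
            model = make_svm(seed=seed)
            model.fit(red.scores, y[tr])
            accs.append(float(np.mean(model.predict(red.transform(X[te])) == y[te])))
            ks.append(red.n_components)
        fold_accs = np.array(accs)
        k = int(np.median(ks))
    else:
        red = pca_reduce(X, target_variance)
        fold_accs = svm_cv_accuracy(red.scores, y, n_folds=n_folds, seed=seed)
        k = red.n_components
    return LayerProbeResult(
        layer_id=layer_id,
        feature_type=feature_type,
        color_mode=color_mode,
        fold_accuracies=fold_accs,
        n_components_retained=k,
        subsample_report=subsample_report,
    )


def probe_layers(
    dataset: LabeledDataset,
    backbone: Backbone,
    layers: Sequence[str] = ALL_LAYERS,
    color_mode: str = "rgb",
    target_variance: float = 0.80,
    n_folds: int = 10,
    seed: int = 0,
    subsample_fraction: float = 0.5,
    subsample_layers: Sequence[str] = ("conv1", "conv2"),
    leakage_free: bool = False,
) -> list[LayerProbeResult]:
    """Activation probe for each requested layer (conv1..conv16, FC1, FC2).

    ``color_mode='gray'`` converts every image through NTSC grayscale before
    feature extraction. The conv1/conv2 activation matrices are subsampled
    to ``subsample_fraction`` of their columns first; the attached
    :class:`SubsampleReport` certifies the reduction preserved the mean.
    """
    unknown = set(layers) - set(ALL_LAYERS)
    if unknown:
        raise ValueError(f"unknown layer ids: {sorted(unknown)}")
    images = list(dataset)
    if color_mode == "gray":
        images = [to_grayscale_ntsc(im) for im in images]
    elif color_mode != "rgb":
        raise ValueError("color_mode must be 'rgb' or 'gray'")
    labels = dataset.labels

    mats = activation_matrix(backbone, images, list(layers))
    results = []
    for layer in layers:
        X = mats.pop(layer)
        report = None
        if layer in subsample_layers and subsample_fraction < 1.0:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, DEPTH_INDEX[layer]])
            )
            X, report = subsample_activations(X, subsample_fraction, rng)
        results.append(
            probe_feature_matrix(
                X,
                labels,
                layer_id=layer,
                feature_type="activation",
                color_mode=color_mode,
                target_variance=target_variance,
                n_folds=n_folds,
                seed=seed,
                leakage_free=leakage_free,
                subsample_report=report,
            )
        )
    return results


@dataclass
class SlopeTestResult:
    """OLS slope of probe accuracy on layer depth, with a two-sided t-test."""

    slope: float
    p_value: float
    intercept: float
    stderr: float
    layer_indices: np.ndarray

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def slope_test(
    results: Sequence,
    depths: Optional[Sequence[float]] = None,
) -> SlopeTestResult:
    """Regress mean accuracy on layer depth; test slope = 0 (two-sided).

    Accepts a list of :class:`LayerProbeResult` (depth taken from the
    conv1..16 -> 1..16, FC1 -> 17, FC2 -> 18 convention) or a plain
    accuracy sequence with explicit ``depths``. Degenerate fits (zero
    residual variance) use the convention p = 1 for zero slope and p = 0
    otherwise.
    """
    if len(results) and isinstance(results[0], LayerProbeResult):
        y = np.array([r.mean_accuracy for r in results], dtype=float)
        x = np.array([r.depth_index for r in results], dtype=float)
    else:
        y = np.asarray(results, dtype=float)
        if depths is None:
            raise ValueError("explicit depths required for plain accuracy input")
        x = np.asarray(depths, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 layers for the slope test")
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0:
        raise ValueError("layer depths are all equal")
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
    else:
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return SlopeTestResult(
        slope=float(slope),
        p_value=p,
        intercept=float(intercept),
        stderr=float(se),
        layer_indices=x,
    )
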