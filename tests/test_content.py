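"""PCA reduction, SVM cross-validation, layer probes, and the depth-slope test."""

import numpy as np
import pytest

import scribbleprobe as sp
from scribbleprobe.content import (
    pca_reduce,
    probe_feature_matrix,
    slope_test,
    svm_cv_accuracy,
)


def _blobs(n_per_class=20, sep=20.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per_class, d))
    b = rng.normal(size=(n_per_class, d)) + sep
    X = np.vstack([a, b])
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return X, y


class TestPCAReduce:
    def test_collinear_data_needs_one_component(self):
        t = np.linspace(-1, 1, 30)[:, None]
        X = t @ np.array([[1.0, 2.0, -0.5]]) + 7.0
        red = pca_reduce(X, 0.80)
        assert red.n_components == 1
        assert red.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_variance_returns_rank(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3)) @ rng.normal(size=(3, 8))  # rank 3
        red = pca_reduce(X, 1.0)
        assert red.n_components == 3

    def test_spectrum_matches_covariance_eigensolver(self):
        """Dual-route check against a brute-force covariance eigendecomposition."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 6))
        red = pca_reduce(X, 0.80)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1)))[::-1]
        assert np.allclose(
            red.explained_variance_ratio[:6], evals / evals.sum(), atol=1e-8
        )

    def test_scores_match_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 40))
        red = pca_reduce(X, 0.9)
        ref = PCA(n_components=red.n_components, svd_solver="full").fit(X)
        scores_ref = ref.transform(X)
        for k in range(red.n_components):  # scores equal up to sign per axis
            assert np.allclose(
                np.abs(red.scores[:, k]), np.abs(scores_ref[:, k]), atol=1e-8
            )

    def test_retained_variance_meets_target(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            X = rng.normal(size=(12, 30)) * rng.uniform(0.1, 5, size=30)
            red = pca_reduce(X, 0.80)
            got = red.explained_variance_ratio[: red.n_components].sum()
            assert got >= 0.80 - 1e-12

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pca_reduce(np.full((5, 4), 3.0), 0.8)


class TestSVMCV:
    def test_separable_blobs_perfect_folds(self):
        X, y = _blobs()
        accs = svm_cv_accuracy(X, y, n_folds=10, seed=0)
        assert accs.shape == (10,)
        assert np.all(accs == 1.0)

    def test_permuted_labels_fall_to_chance(self):
        """Label permutation destroys the signal down to the dummy rate."""
        X, y = _blobs()
        rng = np.random.default_rng(0)
        means = [
            svm_cv_accuracy(X, rng.permutation(y), n_folds=5, seed=s).mean()
            for s in range(20)
        ]
        assert abs(np.mean(means) - sp.dummy_accuracy(y)) < 0.08

    def test_leave_one_out_zero_one_valued(self):
        X, y = _blobs(n_per_class=6)
        accs = svm_cv_accuracy(X, y, n_folds=len(y), seed=0)
        assert accs.shape == (len(y),)
        assert set(np.unique(accs)) <= {0.0, 1.0}

    def test_small_class_advises_fewer_folds(self):
        X, y = _blobs(n_per_class=4)
        with pytest.raises(ValueError, match="lower n_folds"):
            svm_cv_accuracy(X, y, n_folds=10)


class TestProbePipeline:
    def test_feature_permutation_invariance(self):
        """PCA + SVM accuracy is unchanged by reordering feature columns."""
        rng = np.random.default_rng(5)
        X, y = _blobs(n_per_class=15, sep=2.0, d=12, seed=5)
        perm = rng.permutation(X.shape[1])
        r1 = probe_feature_matrix(X, y, "conv1", "activation", "rgb",
                                  n_folds=5, seed=0)
        r2 = probe_feature_matrix(X[:, perm], y, "conv1", "activation", "rgb",
                                  n_folds=5, seed=0)
        assert np.allclose(r1.fold_accuracies, r2.fold_accuracies)
        assert r1.n_components_retained == r2.n_components_retained

    def test_result_summaries_consistent_with_folds(self):
        X, y = _blobs(n_per_class=10, sep=1.0)
        r = probe_feature_matrix(X, y, "conv3", "activation", "gray",
                                 n_folds=5, seed=1)
        assert r.mean_accuracy == pytest.approx(r.fold_accuracies.mean())
        assert r.sd_accuracy == pytest.approx(r.fold_accuracies.std(ddof=1))
        assert r.depth_index == 3

    def test_leakage_free_mode_runs(self):
        X, y = _blobs(n_per_class=10, sep=8.0, d=6)
        r = probe_feature_matrix(X, y, "conv2", "activation", "rgb",
                                 n_folds=5, seed=0, leakage_free=True)
        assert r.fold_accuracies.shape == (5,)
        assert r.mean_accuracy > 0.9

    def test_probe_layers_returns_all_eighteen(self, backbone):
        """Full layer sweep: 16 conv + FC1 + FC2 results in order."""
        params = sp.make_season_params("paperlike")
        ds = sp.generate_dataset(params, {s: 5 for s in sp.SEASONS}, seed=0)
        results = sp.probe_layers(ds, backbone, n_folds=5, seed=0)
        assert len(results) == 18
        assert [r.layer_id for r in results] == list(sp.ALL_LAYERS)
        for r in results[:2]:  # conv1, conv2 were subsampled at 50%
            assert r.subsample_report is not None
            assert r.subsample_report.fraction == 0.5
        assert all(r.subsample_report is None for r in results[2:])

    def test_unknown_layer_rejected(self, backbone, paperlike_small):
        with pytest.raises(ValueError, match="unknown layer"):
            sp.probe_layers(paperlike_small, backbone, layers=["conv99"])


class TestSlopeTest:
    def test_matches_closed_form_and_statsmodels(self):
        """18-point toy table against an independent OLS t-test."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        depths = np.arange(1, 19, dtype=float)
        accs = 0.3 + 0.004 * depths + rng.normal(0, 0.02, size=18)
        res = slope_test(accs, depths=depths)
        fit = sm.OLS(accs, sm.add_constant(depths)).fit()
        assert res.slope == pytest.approx(fit.params[1], rel=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)
        assert res.stderr == pytest.approx(fit.bse[1], rel=1e-8)

    def test_constant_accuracies_degenerate_p_one(self):
        res = slope_test([0.4, 0.4, 0.4, 0.4], depths=[1, 2, 3, 4])
        assert res.slope == 0.0 and res.p_value == 1.0

    def test_exact_line_p_zero(self):
        depths = np.array([1.0, 2.0, 3.0, 4.0])
        res = slope_test(0.1 + 0.05 * depths, depths=depths)
        assert res.slope == pytest.approx(0.05)
        assert res.p_value < 1e-12

    def test_needs_three_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            slope_test([0.1, 0.2], depths=[1, 2])

    def test_accepts_probe_results(self):
        X, y = _blobs(n_per_class=10, sep=5.0)
        results = [
            probe_feature_matrix(X, y, layer, "activation", "rgb",
                                 n_folds=5, seed=0)
            for layer in ("conv1", "conv2", "conv3")
        ]
        res = slope_test(results)
        assert list(res.layer_indices) == [1, 2, 3]
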