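import numpy as np
import pytest

from foggan.evaluation import (
    SimilarityReport,
    classify_correlation_strength,
    correlation_report,
    cumulative_sum_curves,
    feature_distribution_metrics,
    log_mean_std_points,
    pca_compare,
    pearson_correlation_matrix,
    render_figures,
    similarity_report,
)


def _definitional_pearson(x, y):
    """Independent oracle: the raw-sum definition of Pearson's r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestCorrelationMatrix:
    def test_duplicated_column(self):
        x = np.random.default_rng(0).normal(size=100)
        C = pearson_correlation_matrix(np.column_stack([x, x]))
        assert C[0, 1] == pytest.approx(1.0)

    def test_negated_column(self):
        x = np.random.default_rng(0).normal(size=100)
        C = pearson_correlation_matrix(np.column_stack([x, -x]))
        assert C[0, 1] == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        C = pearson_correlation_matrix(np.column_stack([x, y]))
        assert C[0, 1] == pytest.approx(_definitional_pearson(x, y), abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        X = np.random.default_rng(1).normal(size=(200, 5))
        C = pearson_correlation_matrix(X)
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert (np.abs(C) <= 1.0).all()

    def test_constant_column_convention(self):
        X = np.column_stack([np.ones(50), np.random.default_rng(0).normal(size=50)])
        C = pearson_correlation_matrix(X)
        assert C[0, 1] == 0.0 and C[0, 0] == 1.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pearson_correlation_matrix(np.ones((1, 3)))


class TestCorrelationBands:
    @pytest.mark.parametrize(
        "r, band",
        [
            (0.2, "highly significant"),
            (0.16, "highly significant"),
            (0.12, "high"),
            (0.10, "high"),
            (0.05, "moderate"),
            (0.01, "moderate"),
            (0.005, "negligible"),
            (-0.25, "highly significant"),
            (1.0, "highly significant"),
        ],
    )
    def test_band_labels(self, r, band):
        assert classify_correlation_strength(r) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_correlation_strength(1.5)


class TestCorrelationReport:
    def test_self_comparison_zero(self):
        X = np.random.default_rng(0).normal(size=(100, 4))
        rep = correlation_report(X, X)
        np.testing.assert_array_equal(rep.abs_difference, np.zeros((4, 4)))

    def test_same_distribution_sampling_bound(self):
        rng = np.random.default_rng(11)
        cov = np.eye(4) + 0.5
        a = rng.multivariate_normal(np.zeros(4), cov, size=50_000)
        b = rng.multivariate_normal(np.zeros(4), cov, size=50_000)
        rep = correlation_report(a, b)
        assert rep.max_abs_difference < 0.1

    def test_permuted_column_dominates_difference(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5_000, 1))
        X = base + 0.3 * rng.normal(size=(5_000, 4))  # strongly cross-correlated
        Y = X.copy()
        Y[:, 2] = rng.permutation(Y[:, 2])  # destroy column 2's correlations
        rep = correlation_report(X, Y)
        row_sum = rep.abs_difference.sum(axis=1)
        assert row_sum.argmax() == 2

    def test_column_mismatch(self):
        with pytest.raises(ValueError):
            correlation_report(np.zeros((10, 3)), np.zeros((10, 4)))


class TestCumulativeSums:
    def test_definition(self):
        real = np.array([[1.0], [2.0], [3.0]])
        synth = np.zeros((4, 1))
        r, s = cumulative_sum_curves(real, synth, 0)
        assert r.tolist() == [1.0, 3.0, 6.0]
        assert s.tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_final_point_is_column_sum(self):
        rng = np.random.default_rng(5)
        X, Y = rng.normal(size=(67, 3)), rng.normal(size=(31, 3))
        for j in range(3):
            r, s = cumulative_sum_curves(X, Y, j)
            assert len(r) == 67 and len(s) == 31
            assert r[-1] == pytest.approx(X[:, j].sum())
            assert s[-1] == pytest.approx(Y[:, j].sum())

    def test_bad_index(self):
        with pytest.raises(IndexError):
            cumulative_sum_curves(np.zeros((5, 3)), np.zeros((5, 3)), 3)


class TestLogMeanStd:
    def test_log10_arithmetic(self):
        X = np.random.default_rng(0).normal(10.0, 1.0, size=(200_000, 1))
        pts, _ = log_mean_std_points(X, X)
        assert pts[0, 0] == pytest.approx(1.0, abs=0.01)
        assert pts[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_zero_mean_epsilon_rule(self):
        X = np.array([[-1.0], [1.0]])
        pts, _ = log_mean_std_points(X, X)
        assert pts[0, 0] == pytest.approx(np.log10(1e-12))

    def test_identical_matrices(self):
        X = np.random.default_rng(2).normal(size=(50, 3))
        a, b = log_mean_std_points(X, X)
        np.testing.assert_array_equal(a, b)


class TestPca:
    def test_rank_one_ratios(self):
        t = np.random.default_rng(0).normal(size=(500, 1))
        X = t @ np.array([[1.0, 2.0, -1.0]])
        out = pca_compare(X, X, k=2)
        assert out.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert out.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-9)

    def test_identical_projections(self):
        X = np.random.default_rng(1).normal(size=(300, 5))
        out = pca_compare(X, X, k=3)
        np.testing.assert_allclose(out.real_projection, out.synthetic_projection)

    def test_real_projection_centered(self):
        X = np.random.default_rng(2).normal(3.0, 2.0, size=(400, 4))
        out = pca_compare(X, np.random.default_rng(3).normal(size=(100, 4)), k=2)
        np.testing.assert_allclose(out.real_projection.mean(axis=0), 0.0, atol=1e-10)

    def test_isotropic_symmetry(self):
        X = np.random.default_rng(4).normal(size=(100_000, 9))
        out = pca_compare(X, X[:100], k=9)
        np.testing.assert_allclose(out.explained_variance_ratio, 1 / 9, atol=0.01)
        assert (np.diff(out.explained_variance_ratio) <= 1e-15).all()

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            pca_compare(np.zeros((10, 3)), np.zeros((10, 3)), k=4)


class TestDistributionMetrics:
    def test_identical_columns(self):
        X = np.random.default_rng(0).normal(size=(500, 2))
        ks, js = feature_distribution_metrics(X, X)
        np.testing.assert_array_equal(ks, 0.0)
        np.testing.assert_array_equal(js, 0.0)

    def test_disjoint_supports_maximal(self):
        a = np.zeros((200, 1)) + np.random.default_rng(0).uniform(0, 1, (200, 1))
        b = 10.0 + np.random.default_rng(1).uniform(0, 1, (200, 1))
        ks, js = feature_distribution_metrics(a, b)
        assert ks[0] == pytest.approx(1.0)
        assert js[0] == pytest.approx(np.log(2))

    def test_uniform_shift_closed_form(self):
        # CDF gap between U(0,1) and U(0.5,1.5) is exactly 0.5
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, (50_000, 1))
        b = rng.uniform(0.5, 1.5, (50_000, 1))
        ks, _ = feature_distribution_metrics(a, b)
        assert ks[0] == pytest.approx(0.5, abs=0.02)

    def test_bounds_random(self):
        rng = np.random.default_rng(9)
        ks, js = feature_distribution_metrics(
            rng.normal(size=(300, 4)), rng.normal(2, 3, size=(400, 4))
        )
        assert ((ks >= 0) & (ks <= 1)).all()
        assert ((js >= 0) & (js <= np.log(2) + 1e-12)).all()

    def test_empty_error(self):
        with pytest.raises(ValueError):
            feature_distribution_metrics(np.zeros((0, 2)), np.zeros((5, 2)))


class TestSimilarityReport:
    def test_self_comparison_zero_scalars(self):
        X = np.random.default_rng(0).normal(size=(400, 9))
        rep = similarity_report(X, X)
        assert rep.max_abs_correlation_difference == 0.0
        assert rep.mean_ks == 0.0

    def test_disjoint_halves_of_one_corpus(self, preprocessed):
        X = preprocessed.X
        half = len(X) // 2
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(X))
        rep = similarity_report(X[perm[:half]], X[perm[half : 2 * half]])
        assert rep.mean_ks < 0.05

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        rep = similarity_report(rng.normal(size=(300, 9)), rng.normal(size=(200, 9)))
        path = tmp_path / "report.json"
        rep.save(path)
        back = SimilarityReport.load(path)
        assert back.to_dict() == rep.to_dict()

    def test_row_permutation_invariance_except_cumsum(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(300, 4)), rng.normal(size=(250, 4))
        Yp = Y[rng.permutation(len(Y))]
        a, b = similarity_report(X, Y), similarity_report(X, Yp)
        np.testing.assert_allclose(
            a.correlation.synthetic_matrix, b.correlation.synthetic_matrix
        )
        np.testing.assert_allclose(a.ks, b.ks)
        np.testing.assert_allclose(a.js, b.js)
        np.testing.assert_allclose(a.log_points_synthetic, b.log_points_synthetic)

    def test_render_figures(self, tmp_path):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(200, 9)), rng.normal(size=(200, 9))
        rep = similarity_report(X, Y)
        paths = render_figures(X, Y, rep, tmp_path / "figs")
        assert len(paths) == 5
        import os

        assert all(os.path.exists(p) for p in paths)
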