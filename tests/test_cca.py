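"""Canonical correlation analysis: fit, sequential tests, and identities."""

import numpy as np
import pytest

from csflink import cca
from csflink.association import pearson_p, pearson_r
from csflink.cca import (
    CollinearityError,
    cross_loadings,
    eigenvalue,
    fit,
    loadings,
    rao_f,
    redundancy_index,
    wilks_sequence,
)


def random_instance(rng, n=40, p=3, q=5, coupling=0.6):
    x = rng.standard_normal((n, p))
    y = rng.standard_normal((n, q))
    y[:, 0] += coupling * x[:, 0]
    y[:, 1] -= coupling * x[:, 1]
    return x, y


class TestFit:
    def test_bivariate_degenerates_to_pearson(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        model = fit(x, y)
        assert model.correlations[0] == pytest.approx(abs(pearson_r(x, y)), abs=1e-12)

    def test_affine_image_gives_unit_correlations(self, rng):
        x = rng.standard_normal((20, 2))
        m = np.array([[2.0, 1.0], [0.5, -1.0]])
        model = fit(x, x @ m + np.array([3.0, -7.0]))
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-8)

    def test_grid_search_oracle_2x2(self, rng):
        """First correlation matches a dense unit-direction grid search."""
        x = rng.standard_normal((10, 2))
        y = rng.standard_normal((10, 2))
        y[:, 0] += 0.8 * x[:, 0]
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        ys = (y - y.mean(0)) / y.std(0, ddof=1)
        sxx, syy = xs.T @ xs, ys.T @ ys
        sxy = xs.T @ ys
        theta = np.linspace(0, np.pi, 2001)
        a = np.stack([np.cos(theta), np.sin(theta)])  # 2 × G
        num = a.T @ sxy @ a                          # G × G
        da = np.einsum("ig,ij,jg->g", a, sxx, a)
        db = np.einsum("ig,ij,jg->g", a, syy, a)
        grid_max = np.max(np.abs(num) / np.sqrt(np.outer(da, db)))
        model = fit(x, y)
        assert model.correlations[0] == pytest.approx(grid_max, abs=1e-3)

    def test_variates_orthonormal_and_paired(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        s = model.n_functions
        np.testing.assert_allclose(np.corrcoef(model.x_scores.T), np.eye(s), atol=1e-8)
        np.testing.assert_allclose(np.corrcoef(model.y_scores.T), np.eye(s), atol=1e-8)
        cross = np.array(
            [[np.corrcoef(model.x_scores[:, i], model.y_scores[:, j])[0, 1]
              for j in range(s)] for i in range(s)]
        )
        np.testing.assert_allclose(cross, np.diag(model.correlations), atol=1e-8)

    def test_affine_invariance_of_correlations(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        mx = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        my = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        transformed = fit(x @ mx + rng.standard_normal(3), y @ my - 1.0)
        np.testing.assert_allclose(
            transformed.correlations, model.correlations, atol=1e-8
        )

    def test_sign_convention_dominant_loading_positive(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        for k in range(model.n_functions):
            stacked = np.concatenate([model.x_loadings[:, k], model.y_loadings[:, k]])
            assert stacked[np.argmax(np.abs(stacked))] > 0

    def test_rank_deficient_block_names_columns(self, rng):
        x = rng.standard_normal((20, 2))
        y = rng.standard_normal((20, 3))
        y[:, 2] = y[:, 0] + y[:, 1]
        with pytest.raises(CollinearityError, match="ridge"):
            fit(x, y, y_names=["a", "b", "ab"])
        model = fit(x, y, y_names=["a", "b", "ab"], ridge=1e-8)
        assert model.n_functions == 2

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="n > p \\+ q"):
            fit(rng.standard_normal((5, 3)), rng.standard_normal((5, 3)))

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((20, 2))
        x[:, 1] = 4.0
        with pytest.raises(CollinearityError, match="constant"):
            fit(x, rng.standard_normal((20, 2)))


class TestSequentialStatistics:
    def test_wilks_product_form(self):
        r = [0.9, 0.5, 0.1]
        assert wilks_sequence(r, 1) == pytest.approx((1 - 0.81) * (1 - 0.25) * (1 - 0.01))
        assert wilks_sequence(r, 3) == pytest.approx(1 - 0.01)
        assert wilks_sequence([0.0, 0.0], 1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            wilks_sequence(r, 4)

    def test_eigenvalue_form(self):
        assert eigenvalue(0.0) == 0.0
        assert eigenvalue(0.5) == pytest.approx(0.25 / 0.75)
        with pytest.raises(ValueError):
            eigenvalue(1.0)

    def test_rao_f_null_and_errors(self):
        f, df1, df2, p = rao_f(1.0, 3, 8, 36, 1)
        assert f == 0.0 and p == 1.0
        with pytest.raises(ValueError, match="too small"):
            rao_f(0.5, 3, 8, 7, 1)

    def test_rao_f_bivariate_equals_pearson_test(self, rng):
        """p = q = 1: Rao's F is the squared Pearson t with matching p-value."""
        x = rng.standard_normal(24)
        y = 0.4 * x + rng.standard_normal(24)
        r = pearson_r(x, y)
        lam = 1 - r * r
        f, df1, df2, p = rao_f(lam, 1, 1, 24, 1)
        assert df1 == 1.0 and df2 == pytest.approx(22.0)
        t_sq = r * r * (24 - 2) / (1 - r * r)
        assert f == pytest.approx(t_sq, rel=1e-10)
        assert p == pytest.approx(pearson_p(r, 24), rel=1e-10)

    def test_model_wilks_matches_operations(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        for k in range(1, model.n_functions + 1):
            assert model.wilks.loc[k, "wilks"] == pytest.approx(
                wilks_sequence(model.correlations, k)
            )


class TestStructureCoefficients:
    def test_bivariate_loading_is_one(self, rng):
        x = rng.standard_normal(30)
        model = fit(x, 0.7 * x + rng.standard_normal(30))
        assert abs(loadings(model, "x").iloc[0, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_loading_identity_rxx_a(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        rxx = xs.T @ xs / (x.shape[0] - 1)
        np.testing.assert_allclose(
            model.x_loadings, rxx @ model.x_coefficients, atol=1e-10
        )

    def test_orthonormal_block_loadings_equal_coefficients(self, rng):
        # with (near-)identity correlation, loadings ~ coefficients
        x = rng.standard_normal((4000, 3))
        y = rng.standard_normal((4000, 3)) + 0.3 * x
        model = fit(x, y)
        np.testing.assert_allclose(model.x_loadings, model.x_coefficients, atol=0.1)

    def test_cross_loading_identity_and_direct_correlation(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        np.testing.assert_allclose(
            model.x_cross_loadings, model.x_loadings * model.correlations, atol=1e-10
        )
        direct = np.array(
            [[np.corrcoef(x[:, v], model.y_scores[:, k])[0, 1]
              for k in range(model.n_functions)] for v in range(x.shape[1])]
        )
        np.testing.assert_allclose(cross_loadings(model, "x").to_numpy(), direct, atol=1e-10)

    def test_redundancy_identities(self, rng):
        x, y = random_instance(rng)
        model = fit(x, y)
        for k in range(1, model.n_functions + 1):
            ri = redundancy_index(model, "y", k)
            assert 0.0 <= ri <= 1.0
            assert ri == pytest.approx(
                float(np.mean(model.y_cross_loadings[:, k - 1] ** 2)), abs=1e-10
            )
        assert redundancy_index(model, "x", 1) == pytest.approx(
            model.correlations[0] ** 2 * np.mean(model.x_loadings[:, 0] ** 2)
        )
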