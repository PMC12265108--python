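import numpy as np
import pytest

from cisegene.association import (
    corr_to_pvalue,
    max_abs_corr,
    nominal_pass,
    residualize,
    standardize_columns,
)
from cisegene.containers import CovariateMatrix
from .conftest import make_block, make_covariates, make_expression


def ols_snp_pvalue(y, snp, X):
    """Independent oracle: P value of the SNP coefficient from a full
    linear-model fit of y on [1, snp, covariates]."""
    from scipy import stats

    n = y.size
    D = np.column_stack([np.ones(n), snp, X])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    df = n - D.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(D.T @ D)
    t = coef[1] / np.sqrt(cov[1, 1])
    return 2 * stats.t.sf(abs(t), df)


class TestResidualize:
    def test_intercept_only_centers_columns(self, rng):
        M = rng.standard_normal((15, 3))
        out = residualize(M, CovariateMatrix.empty(15))
        np.testing.assert_allclose(out.values, M - M.mean(axis=0), atol=1e-12)
        assert out.df_resid == 15 - 2

    def test_column_in_covariate_span_vanishes(self, rng):
        X = make_covariates(n=20, K=2)
        M = np.column_stack([X.values[:, 0], rng.standard_normal(20)])
        out = residualize(M, X)
        assert np.abs(out.values[:, 0]).max() < 1e-10

    def test_matches_per_column_ols(self, rng):
        M = rng.standard_normal((20, 3))
        X = make_covariates(n=20, K=2)
        out = residualize(M, X)
        D = np.column_stack([np.ones(20), X.values])
        for j in range(3):
            coef, *_ = np.linalg.lstsq(D, M[:, j], rcond=None)
            np.testing.assert_allclose(out.values[:, j], M[:, j] - D @ coef, atol=1e-10)

    def test_collinear_covariates_named(self):
        vals = np.ones((10, 2))
        X = CovariateMatrix(vals, ["a", "b"])
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.random.default_rng(0).standard_normal((10, 1)), X)


class TestMaxAbsCorr:
    def test_single_snp_is_plain_correlation(self, rng):
        y = rng.standard_normal(30)
        g = rng.standard_normal((30, 1))
        X = CovariateMatrix.empty(30)
        yr = residualize(y, X).values[:, 0]
        gr, _ = standardize_columns(residualize(g, X).values)
        t, lead = max_abs_corr(yr, gr)
        expected = abs(np.corrcoef(y, g[:, 0])[0, 1])
        assert t == pytest.approx(expected, abs=1e-12)
        assert lead == 0

    def test_duplicated_snp_does_not_change_max(self, rng):
        y = rng.standard_normal(30)
        G = rng.standard_normal((30, 4))
        X = CovariateMatrix.empty(30)
        yr = residualize(y, X).values[:, 0]
        g1, _ = standardize_columns(residualize(G, X).values)
        g2, _ = standardize_columns(residualize(np.column_stack([G, G[:, 0]]), X).values)
        assert max_abs_corr(yr, g1)[0] == pytest.approx(max_abs_corr(yr, g2)[0], abs=1e-12)

    def test_matches_naive_per_snp_loop(self, rng):
        y = rng.standard_normal(30)
        G = rng.standard_normal((30, 5))
        X = make_covariates(n=30, K=2)
        D = np.column_stack([np.ones(30), X.values])
        coef_y, *_ = np.linalg.lstsq(D, y, rcond=None)
        ry = y - D @ coef_y
        best = 0.0
        for k in range(5):
            coef_g, *_ = np.linalg.lstsq(D, G[:, k], rcond=None)
            rg = G[:, k] - D @ coef_g
            best = max(best, abs(np.corrcoef(ry, rg)[0, 1]))
        gr, _ = standardize_columns(residualize(G, X).values)
        t, _ = max_abs_corr(residualize(y, X).values[:, 0], gr)
        assert t == pytest.approx(best, abs=1e-10)


class TestCorrToPvalue:
    def test_zero_correlation_gives_one(self):
        assert corr_to_pvalue(0.0, 20, 2) == pytest.approx(1.0)

    def test_unit_correlation_gives_zero(self):
        assert corr_to_pvalue(1.0, 20, 2) == 0.0

    def test_matches_full_ols_fit(self, rng):
        n, K = 20, 2
        X = rng.standard_normal((n, K))
        snp = rng.integers(0, 3, n).astype(float)
        y = 0.4 * snp + X @ [0.5, -0.3] + rng.standard_normal(n)
        cov = CovariateMatrix(X, ["c1", "c2"])
        ry = residualize(y, cov).values[:, 0]
        rg, _ = standardize_columns(residualize(snp, cov).values)
        r = (rg[:, 0] @ ry) / np.sqrt(ry @ ry * n)
        assert corr_to_pvalue(r, n, K) == pytest.approx(ols_snp_pvalue(y, snp, X), abs=1e-10)

    def test_strictly_decreasing_in_abs_r(self):
        grid = np.linspace(0, 0.99, 50)
        p = corr_to_pvalue(grid, 30, 3)
        assert np.all(np.diff(p) < 0)

    def test_too_few_degrees_of_freedom(self):
        with pytest.raises(ValueError, match="df"):
            corr_to_pvalue(0.5, 4, 2)


class TestNominalPass:
    def test_row_count_and_ols_agreement(self, rng):
        expr = make_expression(n=30, p=2)
        blocks = [make_block(g, n=30, q=3, seed=j) for j, g in enumerate(expr.gene_ids)]
        X = make_covariates(n=30, K=2)
        table = nominal_pass(expr, blocks, X)
        assert len(table) == 6
        for _, row in table.iterrows():
            j = expr.gene_ids.index(row.gene_id)
            block = blocks[j]
            k = block.snp_ids.index(row.snp_id)
            expected = ols_snp_pvalue(expr.values[:, j], block.dosages[:, k], X.values)
            assert row.pvalue == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_joint_sample_relabeling(self, rng):
        expr = make_expression(n=25, p=2)
        blocks = [make_block(g, n=25, q=3, seed=j) for j, g in enumerate(expr.gene_ids)]
        X = make_covariates(n=25, K=2)
        base = nominal_pass(expr, blocks, X)
        perm = rng.permutation(25)
        expr2 = make_expression(n=25, p=2)
        expr2.values = expr2.values[perm]
        blocks2 = [b.subset_snps(np.arange(b.n_snps)) for b in blocks]
        for b in blocks2:
            b.dosages = b.dosages[perm]
        X2 = CovariateMatrix(X.values[perm], X.covariate_ids)
        jointly = nominal_pass(expr2, blocks2, X2)
        np.testing.assert_allclose(base.pvalue, jointly.pvalue, atol=1e-10)


def test_max_corr_equals_min_pvalue_correspondence(rng):
    """max |r| over SNPs and min per-SNP linear-model P value pick the same
    SNP and agree numerically after the t transform."""
    expr = make_expression(n=40, p=1)
    block = make_block("G0", n=40, q=6, seed=5)
    X = make_covariates(n=40, K=2)
    ry = residualize(expr.values, X).values[:, 0]
    rg, ok = standardize_columns(residualize(block.dosages, X).values)
    t, lead = max_abs_corr(ry, rg[:, ok])
    p_from_t = corr_to_pvalue(t, 40, 2)
    p_each = [
        ols_snp_pvalue(expr.values[:, 0], block.dosages[:, k], X.values) for k in range(6)
    ]
    assert p_from_t == pytest.approx(min(p_each), abs=1e-10)
    assert lead == int(np.argmin(p_each))
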