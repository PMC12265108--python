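import time
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from cisegene.association import corr_to_pvalue
from cisegene.containers import CovariateMatrix, MethodConfig
from cisegene.egene import (
    gene_stats,
    permutation_indices,
    permute_rows,
    run_clipper,
    run_standard,
)
from cisegene.simulate import SimConfig, simulate_dataset
from .conftest import make_block, make_covariates, make_expression


def naive_standard_pvalues(expr, blocks, X, B, seed):
    """Independent oracle: per-gene, per-permutation loop with explicit
    residualization of each permuted expression column and a per-SNP
    correlation loop. Shares only the permutation stream with the fast path."""
    n = expr.n_samples
    D = np.column_stack([np.ones(n), X.values]) if X.n_covariates else np.ones((n, 1))

    def resid(v):
        coef, *_ = np.linalg.lstsq(D, v, rcond=None)
        return v - D @ coef

    def max_corr(y_res, block):
        best = 0.0
        for k in range(block.n_snps):
            g_res = resid(block.dosages[:, k])
            if g_res.std() < 1e-12:
                continue
            best = max(best, abs(np.corrcoef(y_res, g_res)[0, 1]))
        return best

    perms = permutation_indices(n, B, seed)
    pvals = {}
    for j, gid in enumerate(expr.gene_ids):
        block = next(b for b in blocks if b.gene_id == gid)
        t_exp = max_corr(resid(expr.values[:, j]), block)
        exceed = 0
        for b in range(B):
            y_perm = expr.values[perms[b], j]
            if max_corr(resid(y_perm), block) >= t_exp:
                exceed += 1
        pvals[gid] = (1 + exceed) / (B + 1)
    return pvals


class TestPermutations:
    def test_reproducible_from_seed(self):
        a = permutation_indices(10, 3, seed=7)
        b = permutation_indices(10, 3, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, permutation_indices(10, 3, seed=8))

    def test_each_replicate_is_a_permutation(self):
        for perm in permutation_indices(15, 5, seed=1):
            assert sorted(perm) == list(range(15))

    def test_column_means_conserved(self, rng):
        M = rng.standard_normal((12, 4))
        for copy in permute_rows(M, 3, seed=2):
            np.testing.assert_allclose(copy.mean(axis=0), M.mean(axis=0), atol=1e-12)

    def test_single_snp_null_pvalues_uniform(self):
        """With one independent Gaussian 'SNP', the permutation scores mapped
        through the t transform are uniform (KS test at alpha = 0.01)."""
        g = np.random.default_rng(0)
        n, B = 80, 400
        expr = make_expression(n=n, p=1, seed=10)
        block = make_block("G0", n=n, q=1, seed=11)
        X = CovariateMatrix.empty(n)
        stats, _ = gene_stats(
            expr, [block], X, MethodConfig(variant="clipper", B=B, seed=3)
        )
        p_bg = corr_to_pvalue(stats[0].t_bg, n, 0)
        assert sps.kstest(p_bg, "uniform").pvalue > 0.01


class TestRunStandard:
    def test_matches_naive_loop_exactly(self):
        """Fast matrix-aggregated path vs a per-gene/per-permutation loop."""
        n, B = 25, 50
        expr = make_expression(n=n, p=20, seed=3)
        blocks = [
            make_block(g, n=n, q=4, seed=100 + j, tss=t[1])
            for j, (g, t) in enumerate(zip(expr.gene_ids, expr.tss))
        ]
        X = make_covariates(n=n, K=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_standard(expr, blocks, X, MethodConfig(variant="standard", B=B, seed=9))
        expected = naive_standard_pvalues(expr, blocks, X, B, seed=9)
        assert len(res) == 20
        for r in res:
            assert r.gene_pvalue == expected[r.gene_id]

    def test_proportions_formula_extremes(self):
        # a huge planted effect beats every permutation -> p = 1/(B+1)
        n, B = 60, 30
        g = np.random.default_rng(5)
        snp = g.integers(0, 3, n).astype(float)
        expr = make_expression(n=n, p=1, seed=6)
        expr.values[:, 0] = 5 * snp + 0.1 * g.standard_normal(n)
        block = make_block("G0", n=n, q=1, seed=7)
        block.dosages[:, 0] = snp
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_standard(
                expr, [block], CovariateMatrix.empty(n), MethodConfig("standard", B=B, seed=1)
            )
        assert res[0].gene_pvalue == pytest.approx(1 / (B + 1))

    def test_invariant_to_gene_ordering(self):
        n, B = 30, 20
        expr = make_expression(n=n, p=5, seed=8)
        blocks = [
            make_block(g, n=n, q=3, seed=j, tss=t[1])
            for j, (g, t) in enumerate(zip(expr.gene_ids, expr.tss))
        ]
        X = make_covariates(n=n, K=1)
        cfg = MethodConfig("standard", B=B, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res1 = {r.gene_id: r.gene_pvalue for r in run_standard(expr, blocks, X, cfg)}
            order = [3, 1, 4, 0, 2]
            expr2 = expr.subset_genes(np.array(order))
            res2 = {
                r.gene_id: r.gene_pvalue
                for r in run_standard(expr2, [blocks[i] for i in order], X, cfg)
            }
        assert res1 == res2

    def test_genes_without_snps_are_excluded_not_failed(self):
        n = 30
        expr = make_expression(n=n, p=2)
        blocks = [make_block("G0", n=n, q=3)]  # G1 has no block
        with pytest.warns(UserWarning, match="no usable local SNPs"):
            res = run_standard(
                expr, blocks, CovariateMatrix.empty(n), MethodConfig("standard", B=100, seed=0)
            )
        assert [r.gene_id for r in res] == ["G0"]


class TestRunClipper:
    def test_warns_for_small_samples(self):
        expr = make_expression(n=30, p=2)
        blocks = [make_block(g, n=30, q=3, seed=j) for j, g in enumerate(expr.gene_ids)]
        with pytest.warns(UserWarning, match="n > 450"):
            run_clipper(expr, blocks, make_covariates(n=30, K=1), MethodConfig("clipper", B=1))

    def test_strong_signal_always_discovered(self):
        """A SNP explaining 20% of expression variance at n = 800 must be
        called, with plenty of genes around for the contrast null."""
        cfg = SimConfig(
            n=800, p=150, snps_per_gene=20, pve_genotype=0.2, pve_covariates=0.3,
            egene_fraction=0.3, effect_scaling="realized", seed=21,
        )
        expr, blocks, cov, truth = simulate_dataset(cfg)
        res = run_clipper(expr, blocks, cov, MethodConfig("clipper", B=1, seed=5))
        called = {r.gene_id for r in res if r.is_egene}
        true_egenes = {g for g, e in zip(expr.gene_ids, truth.is_egene) if e}
        assert true_egenes <= called

    def test_robust_to_choice_of_B(self):
        """B = 1 and B = 20 select nearly the same eGenes (Jaccard >= 0.9)."""
        cfg = SimConfig(
            n=600, p=200, snps_per_gene=30, pve_genotype=0.05, pve_covariates=0.4,
            egene_fraction=0.25, effect_scaling="realized", seed=13,
        )
        expr, blocks, cov, _ = simulate_dataset(cfg)
        sets = []
        for B in (1, 20):
            res = run_clipper(expr, blocks, cov, MethodConfig("clipper", B=B, seed=31))
            sets.append({r.gene_id for r in res if r.is_egene})
        jaccard = len(sets[0] & sets[1]) / len(sets[0] | sets[1])
        assert jaccard >= 0.9

    def test_variants_agree_in_distribution_under_null(self):
        """Permute-then-residualize and residualize-then-permute produce the
        same null distribution of background scores (KS test)."""
        n, B = 60, 150
        expr = make_expression(n=n, p=1, seed=2)
        block = make_block("G0", n=n, q=5, seed=3)
        X = make_covariates(n=n, K=2)
        s_std, _ = gene_stats(expr, [block], X, MethodConfig("standard", B=B, seed=17))
        s_cl, _ = gene_stats(expr, [block], X, MethodConfig("clipper", B=B, seed=18))
        assert sps.ks_2samp(s_std[0].t_bg, s_cl[0].t_bg).pvalue > 0.01


def test_runtime_scales_linearly_in_B():
    """Doubling B should not much more than double the wall time."""
    n, p, q = 150, 40, 40
    expr = make_expression(n=n, p=p, seed=30)
    blocks = [
        make_block(g, n=n, q=q, seed=200 + j, tss=t[1])
        for j, (g, t) in enumerate(zip(expr.gene_ids, expr.tss))
    ]
    X = make_covariates(n=n, K=3)

    def timed(B):
        best = np.inf
        for _ in range(3):
            t0 = time.perf_counter()
            gene_stats(expr, blocks, X, MethodConfig("clipper", B=B, seed=1))
            best = min(best, time.perf_counter() - t0)
        return best

    t40, t80 = timed(40), timed(80)
    assert t80 / t40 <= 2.6
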