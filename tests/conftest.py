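import numpy as np
import pytest

from cisegene.containers import CisGenotypeBlock, CovariateMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_expression(n=30, p=4, seed=0, chrom="chr1", spacing=3_000_000):
    g = np.random.default_rng(seed)
    return ExpressionMatrix(
        g.standard_normal((n, p)),
        [f"S{i}" for i in range(n)],
        [f"G{j}" for j in range(p)],
        [(chrom, 1_500_000 + j * spacing) for j in range(p)],
    )


def make_block(gene_id="G0", n=30, q=5, seed=0, tss=1_500_000):
    g = np.random.default_rng(seed + 1)
    dosages = g.integers(0, 3, size=(n, q)).astype(float)
    return CisGenotypeBlock(
        gene_id,
        dosages,
        [f"{gene_id}_snp{k}" for k in range(q)],
        [tss - 400_000 + 200_000 * k for k in range(q)],
    )


def make_covariates(n=30, K=2, seed=0):
    g = np.random.default_rng(seed + 2)
    if K == 0:
        return CovariateMatrix.empty(n)
    return CovariateMatrix(g.standard_normal((n, K)), [f"C{k}" for k in range(K)])


@pytest.fixture
def toy_data():
    """Aligned 30-sample, 4-gene, 5-SNP-per-gene data with 2 covariates."""
    expr = make_expression()
    blocks = [make_block(g, tss=t[1], seed=j) for j, (g, t) in enumerate(zip(expr.gene_ids, expr.tss))]
    cov = make_covariates()
    return expr, blocks, cov
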