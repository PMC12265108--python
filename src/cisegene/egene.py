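"""The two permutation-based eGene callers.

Both variants score every gene by the maximum absolute partial correlation
between its expression and its local SNP dosages (T_exp), and compare it
with the same statistic on B row-permuted copies of the expression
(T_bg[1..B]); one permutation is shared by all genes within a replicate,
which is what lets the scan be expressed as matrix-matrix products.

They differ in a deliberate way:

* standard variant — the *raw* expression is permuted first and then
  residualized against the covariates (the classic direct-permutation
  scheme); the gene-level P value is the proportions formula
  ``(1 + #{b : T_bg[b] >= T_exp}) / (B + 1)`` followed by Storey/BH/BY
  q values. Default B = 1000. Suitable for any sample size.
* clipper variant — the expression is residualized once and the residuals
  are permuted; T_exp - max_b T_bg forms a contrast score fed to the
  P-value-free FDR threshold (see :mod:`cisegene.fdr`). Designed for large
  sample sizes (> 450) where B = 1 already suffices.

Genotypes are residualized once and held fixed across permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .association import residualize, standardize_columns
from .containers import (
    CisGenotypeBlock,
    CovariateMatrix,
    EGeneResult,
    ExpressionMatrix,
    GeneStat,
    MethodConfig,
)
from .fdr import bh_adjust, by_adjust, call_egenes, clipper_threshold, storey_qvalue

__all__ = ["permutation_indices", "permute_rows", "run_standard", "run_clipper", "gene_stats"]


def permutation_indices(n: int, B: int, seed: int) -> np.ndarray:
    """B uniform row permutations of range(n), one per replicate.

    Replicate ``b`` draws from its own counter-derived stream of the master
    seed, so any replicate is reproducible in isolation.
    """
    out = np.empty((B, n), dtype=np.intp)
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        out[b] = rng.permutation(n)
    return out


def permute_rows(M: np.ndarray, B: int, seed: int):
    """Lazily yield B row-permuted copies of ``M`` (shared across columns)."""
    M = np.asarray(M)
    for perm in permutation_indices(M.shape[0], B, seed):
        yield M[perm]


@dataclass
class _Prepared:
    gene_index: list[int]          # columns of expr tested
    G_list: list[np.ndarray]       # standardized residual dosages per tested gene
    snp_ids: list[list[str]]
    excluded: list[str]            # gene ids dropped (no usable SNPs)
    G_stack: np.ndarray | None     # (p, q, n) if all genes share q


def _prepare_genotypes(
    expr: ExpressionMatrix, blocks: list[CisGenotypeBlock], X: CovariateMatrix
) -> _Prepared:
    by_gene = {b.gene_id: b for b in blocks}
    gene_index: list[int] = []
    G_list: list[np.ndarray] = []
    snp_ids: list[list[str]] = []
    excluded: list[str] = []
    for j, gid in enumerate(expr.gene_ids):
        block = by_gene.get(gid)
        if block is None or block.n_snps == 0:
            excluded.append(gid)
            continue
        res = residualize(block.dosages, X)
        G_std, ok = standardize_columns(res.values)
        if not ok.any():
            excluded.append(gid)
            continue
        gene_index.append(j)
        G_list.append(G_std[:, ok])
        snp_ids.append([s for s, keep in zip(block.snp_ids, ok) if keep])
    if excluded:
        warnings.warn(
            f"{len(excluded)} gene(s) with no usable local SNPs excluded from testing"
        )
    qs = {g.shape[1] for g in G_list}
    G_stack = None
    if len(qs) == 1 and G_list:
        G_stack = np.ascontiguousarray(np.stack([g.T for g in G_list]))  # (p, q, n)
    return _Prepared(gene_index, G_list, snp_ids, excluded, G_stack)


def _scores(prep: _Prepared, Z: np.ndarray) -> np.ndarray:
    """Per-gene max |corr| between standardized expression columns Z and
    each gene's standardized residual dosages. Z columns must be unit
    population variance; Z[:, k] corresponds to prep.gene_index[k]."""
    n = Z.shape[0]
    if prep.G_stack is not None:
        # batched (p, q, n) @ (p, n, 1) -> (p, q)
        prods = np.matmul(prep.G_stack, Z.T[:, :, None])[:, :, 0]
        return np.abs(prods).max(axis=1) / n
    return np.array(
        [np.abs(G.T @ Z[:, k]).max() / n for k, G in enumerate(prep.G_list)]
    )


_CHUNK = 32  # permutations scored per batched product (keeps G_stack reads low)


def _scores_chunk(prep: _Prepared, Zbuf: np.ndarray, nb: int) -> np.ndarray:
    """Scores for ``nb`` permutations at once. ``Zbuf`` is (n, p, chunk)
    with standardized columns; returns (p, nb)."""
    n = Zbuf.shape[0]
    Zc = Zbuf[:, :, :nb]
    if prep.G_stack is not None:
        prods = np.matmul(prep.G_stack, Zc.transpose(1, 0, 2))  # (p, q, nb)
        return np.abs(prods).max(axis=1) / n
    return np.stack(
        [np.abs(G.T @ Zc[:, k, :]).max(axis=0) / n for k, G in enumerate(prep.G_list)]
    )


def _standardize_or_nan(R: np.ndarray) -> np.ndarray:
    Z, ok = standardize_columns(R)
    if not ok.all():
        Z[:, ~ok] = np.nan
    return Z


def gene_stats(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig,
) -> tuple[list[GeneStat], list[str]]:
    """Experimental and background scores for every testable gene.

    Dispatches on ``config.variant`` for the permute/residualize order.
    Returns (stats, excluded_gene_ids).
    """
    prep = _prepare_genotypes(expr, blocks, X)
    n = expr.n_samples
    B = int(config.B)  # type: ignore[arg-type]

    expr_res = residualize(expr.values, X)
    Z0_full = _standardize_or_nan(expr_res.values)
    Z0 = Z0_full[:, prep.gene_index]
    t_exp = _scores(prep, np.nan_to_num(Z0))

    t_bg = np.empty((len(prep.gene_index), B))
    perms = permutation_indices(n, B, config.seed)
    Zbuf = np.empty((n, len(prep.gene_index), min(_CHUNK, B)))
    if config.variant == "standard":
        # permute raw expression, then residualize each permuted copy
        D = (
            np.column_stack([np.ones(n), X.values])
            if X.n_covariates
            else np.ones((n, 1))
        )
        D_pinv = np.linalg.pinv(D)
        Y = expr.values[:, prep.gene_index]
        for start in range(0, B, _CHUNK):
            nb = min(_CHUNK, B - start)
            for i in range(nb):
                Yp = Y[perms[start + i]]
                Rp = Yp - D @ (D_pinv @ Yp)
                Zbuf[:, :, i] = np.nan_to_num(_standardize_or_nan(Rp))
            t_bg[:, start : start + nb] = _scores_chunk(prep, Zbuf, nb)
    else:
        # residualize once, permute the residuals
        Z0c = np.nan_to_num(Z0)
        for start in range(0, B, _CHUNK):
            nb = min(_CHUNK, B - start)
            for i in range(nb):
                Zbuf[:, :, i] = Z0c[perms[start + i]]
            t_bg[:, start : start + nb] = _scores_chunk(prep, Zbuf, nb)

    stats: list[GeneStat] = []
    degenerate: list[str] = []
    for k, j in enumerate(prep.gene_index):
        gid = expr.gene_ids[j]
        if np.isnan(Z0_full[0, j]):
            degenerate.append(gid)
            continue
        G = prep.G_list[k]
        lead = int(np.argmax(np.abs(G.T @ Z0[:, k]) / n))
        stats.append(
            GeneStat(
                gene_id=gid,
                t_exp=float(min(t_exp[k], 1.0)),
                t_bg=np.minimum(t_bg[k], 1.0),
                lead_snp=prep.snp_ids[k][lead],
                q_j=G.shape[1],
            )
        )
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} gene(s) with zero residual expression variance excluded"
        )
    return stats, prep.excluded + degenerate


_ADJUSTERS = {"storey": storey_qvalue, "bh": bh_adjust, "by": by_adjust}


def run_standard(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig | None = None,
) -> list[EGeneResult]:
    """Direct-permutation scan with proportions gene-level P values."""
    config = config or MethodConfig(variant="standard")
    if config.variant != "standard":
        raise ValueError("config.variant must be 'standard'")
    stats, _ = gene_stats(expr, blocks, X, config)
    B = int(config.B)  # type: ignore[arg-type]
    p = np.array([(1 + np.sum(s.t_bg >= s.t_exp)) / (B + 1) for s in stats])
    q = _ADJUSTERS[config.fdr_procedure](p)
    calls = call_egenes(q, config.target_fdr)
    return [
        EGeneResult(
            gene_id=s.gene_id,
            gene_pvalue=float(p[i]),
            q_value=float(q[i]),
            is_egene=bool(calls[i]),
            method=f"standard_B{B}_{config.fdr_procedure}",
            lead_snp=s.lead_snp,
            statistic=s.t_exp,
        )
        for i, s in enumerate(stats)
    ]


def run_clipper(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig | None = None,
) -> list[EGeneResult]:
    """Contrastive scan: residualize once, permute residuals, threshold
    T_exp - max_b T_bg with the symmetry-based FDR estimator."""
    config = config or MethodConfig(variant="clipper")
    if config.variant != "clipper":
        raise ValueError("config.variant must be 'clipper'")
    if expr.n_samples <= 450:
        warnings.warn(
            f"clipper variant is recommended only for n > 450 (n = {expr.n_samples}); "
            "consider the standard variant"
        )
    stats, _ = gene_stats(expr, blocks, X, config)
    contrast = clipper_threshold(stats, config.target_fdr)
    calls = call_egenes(contrast.q_values, config.target_fdr)
    return [
        EGeneResult(
            gene_id=s.gene_id,
            contrast_score=float(contrast.contrast_scores[i]),
            q_value=float(contrast.q_values[i]),
            is_egene=bool(calls[i]),
            method=f"clipper_B{config.B}",
            lead_snp=s.lead_snp,
            statistic=s.t_exp,
        )
        for i, s in enumerate(stats)
    ]
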