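"""Benchmark gene-level procedures the permutation callers are compared to.

* beta approximation — fit a Beta distribution to the B permutation minima
  of the per-gene nominal P value and read the gene-level P value off its
  CDF (higher resolution than the proportions formula at the same B).
* effective-number-of-tests correction — Bonferroni with the number of
  local SNPs replaced by an eigenvalue-based effective count per gene.
* Simes' rule — min_k (m p_(k) / k) over a gene's SNP P values.
* naive all-pairs calling — BH across every gene-SNP pair, a gene called
  if any of its pairs is significant; known NOT to control the gene-level
  FDR (kept as a negative control).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .association import corr_to_pvalue, nominal_pass
from .containers import (
    CisGenotypeBlock,
    CovariateMatrix,
    EGeneResult,
    ExpressionMatrix,
    GeneStat,
    MethodConfig,
)
from .egene import _ADJUSTERS, gene_stats
from .fdr import bh_adjust, call_egenes

__all__ = [
    "beta_gene_pvalue",
    "eigenmt_gene_pvalue",
    "simes_gene_pvalue",
    "naive_matrixeqtl_egenes",
    "run_beta",
    "run_eigenmt",
    "run_simes",
    "run_naive",
]


def fit_beta_mle(x: np.ndarray) -> tuple[float, float, bool]:
    """Beta(a, b) maximum-likelihood fit on (0,1) data, moment-matched start."""
    x = np.asarray(x, dtype=float)
    x = np.clip(x, 1e-300, 1 - 1e-16)
    m, v = x.mean(), x.var()
    if v <= 0:
        return 1.0, 1.0, False
    common = m * (1 - m) / v - 1
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    try:
        a, b, _, _ = sps.beta.fit(x, a0, b0, floc=0, fscale=1)
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            return float(a), float(b), True
    except Exception:  # scipy raises a few different things on pathological data
        pass
    return a0, b0, False


def beta_gene_pvalue(p_min_obs: float, p_min_perm: np.ndarray) -> float:
    """Gene-level P value via a Beta fit to the permutation minima.

    Falls back to the proportions formula with a warning if the fit fails.
    """
    p_min_perm = np.asarray(p_min_perm, dtype=float)
    a, b, converged = fit_beta_mle(p_min_perm)
    if not converged:
        warnings.warn("beta fit did not converge; falling back to proportions")
        B = p_min_perm.size
        return float((1 + np.sum(p_min_perm <= p_min_obs)) / (B + 1))
    return float(sps.beta.cdf(p_min_obs, a, b))


def eigenmt_gene_pvalue(
    block: CisGenotypeBlock,
    p_min: float,
    var_threshold: float = 0.99,
    window: int = 200,
) -> float:
    """Bonferroni with an eigenvalue-based effective number of local SNPs.

    SNPs are split into consecutive non-overlapping windows; in each, the
    effective count is the smallest k whose top-k eigenvalues of the SNP
    correlation matrix capture ``var_threshold`` of the total variance.
    """
    G = block.dosages
    keep = G.std(axis=0) > 0
    G = G[:, keep]
    if G.shape[1] == 0:
        return min(1.0, p_min)
    m_eff_total = 0
    for start in range(0, G.shape[1], window):
        W = G[:, start : start + window]
        corr = np.corrcoef(W, rowvar=False)
        corr = np.atleast_2d(corr)
        eig = np.linalg.eigvalsh(corr)[::-1]
        eig = np.clip(eig, 0, None)
        frac = np.cumsum(eig) / eig.sum()
        m_eff_total += int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    return min(1.0, p_min * m_eff_total)


def simes_gene_pvalue(p: np.ndarray) -> float:
    """Simes' combined P value: min_k m p_(k) / k, capped at 1."""
    p = np.sort(np.asarray(p, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("need at least one P value")
    return float(min(1.0, (m * p / np.arange(1, m + 1)).min()))


def naive_matrixeqtl_egenes(pairs, target_fdr: float) -> dict[str, bool]:
    """All-pairs BH; a gene is called iff any of its pairs is significant."""
    q = bh_adjust(pairs["pvalue"].to_numpy())
    sig = q <= target_fdr
    out: dict[str, bool] = {}
    for gid, s in zip(pairs["gene_id"], sig):
        out[gid] = out.get(gid, False) or bool(s)
    return out


# ---------------------------------------------------------------- drivers


def _finalize(gene_ids, lead, stat, p, config: MethodConfig, label: str) -> list[EGeneResult]:
    q = _ADJUSTERS[config.fdr_procedure](np.asarray(p))
    calls = call_egenes(q, config.target_fdr)
    return [
        EGeneResult(
            gene_id=g,
            gene_pvalue=float(p[i]),
            q_value=float(q[i]),
            is_egene=bool(calls[i]),
            method=label,
            lead_snp=lead[i],
            statistic=float(stat[i]),
        )
        for i, g in enumerate(gene_ids)
    ]


def run_beta(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig | None = None,
    stats: list[GeneStat] | None = None,
) -> list[EGeneResult]:
    """Direct permutations + beta approximation of the min-P null.

    ``stats`` may carry precomputed scores from :func:`cisegene.egene.gene_stats`
    (standard variant) to avoid repeating the permutations.
    """
    config = config or MethodConfig(variant="standard")
    if stats is None:
        stats, _ = gene_stats(expr, blocks, X, config)
    n, K = expr.n_samples, X.n_covariates
    p = np.array(
        [
            beta_gene_pvalue(
                corr_to_pvalue(s.t_exp, n, K), corr_to_pvalue(s.t_bg, n, K)
            )
            for s in stats
        ]
    )
    return _finalize(
        [s.gene_id for s in stats],
        [s.lead_snp for s in stats],
        [s.t_exp for s in stats],
        p,
        config,
        f"beta_B{config.B}_{config.fdr_procedure}",
    )


def run_eigenmt(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig | None = None,
    var_threshold: float = 0.99,
    window: int = 200,
) -> list[EGeneResult]:
    """Effective-test-count Bonferroni per gene, then FDR across genes
    (BH by default, matching the original tool)."""
    config = config or MethodConfig(variant="standard", B=1, fdr_procedure="bh")
    pairs = nominal_pass(expr, blocks, X)
    by_gene = {b.gene_id: b for b in blocks}
    gene_ids, lead, stat, p = [], [], [], []
    for gid, grp in pairs.groupby("gene_id", sort=False):
        i = int(np.argmin(grp["pvalue"].to_numpy()))
        gene_ids.append(gid)
        lead.append(grp["snp_id"].iloc[i])
        stat.append(abs(grp["r"].iloc[i]))
        p.append(
            eigenmt_gene_pvalue(
                by_gene[gid], float(grp["pvalue"].iloc[i]), var_threshold, window
            )
        )
    return _finalize(gene_ids, lead, stat, p, config, f"eigenmt_{config.fdr_procedure}")


def run_simes(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig | None = None,
) -> list[EGeneResult]:
    """Simes gene-level P values, then FDR across genes (TreeQTL-style;
    Benjamini-Yekutieli by default as in TreeQTL, Storey available)."""
    config = config or MethodConfig(variant="standard", B=1, fdr_procedure="by")
    pairs = nominal_pass(expr, blocks, X)
    gene_ids, lead, stat, p = [], [], [], []
    for gid, grp in pairs.groupby("gene_id", sort=False):
        pv = grp["pvalue"].to_numpy()
        i = int(np.argmin(pv))
        gene_ids.append(gid)
        lead.append(grp["snp_id"].iloc[i])
        stat.append(abs(grp["r"].iloc[i]))
        p.append(simes_gene_pvalue(pv))
    return _finalize(gene_ids, lead, stat, p, config, f"simes_{config.fdr_procedure}")


def run_naive(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
    config: MethodConfig | None = None,
) -> list[EGeneResult]:
    """Matrix eQTL-style naive eGene calling (negative control for FDR)."""
    config = config or MethodConfig(variant="standard", B=1)
    pairs = nominal_pass(expr, blocks, X)
    called = naive_matrixeqtl_egenes(pairs, config.target_fdr)
    out = []
    for gid, grp in pairs.groupby("gene_id", sort=False):
        i = int(np.argmin(grp["pvalue"].to_numpy()))
        out.append(
            EGeneResult(
                gene_id=gid,
                gene_pvalue=float(grp["pvalue"].iloc[i]),
                q_value=np.nan,
                is_egene=called[gid],
                method="naive_allpairs_bh",
                lead_snp=grp["snp_id"].iloc[i],
                statistic=float(abs(grp["r"].iloc[i])),
            )
        )
    return out
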