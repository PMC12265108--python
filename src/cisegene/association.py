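"""Residualization and matrix-aggregated correlation machinery.

Both eGene callers exploit the one-to-one monotone correspondence between
the absolute partial correlation |r| of expression and a SNP dosage (both
residualized on the covariates) and the two-sided P value of the SNP
coefficient in the linear model ``y ~ 1 + snp + covariates``:

    t = r * sqrt(df) / sqrt(1 - r^2),   df = n - K - 2,

with ``t`` Student-t distributed under the null. Because of this, "max |r|
over local SNPs" and "min P value over local SNPs" are interchangeable, and
per-gene association scans reduce to matrix-matrix correlation products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CisGenotypeBlock, CovariateMatrix, ExpressionMatrix

__all__ = [
    "ResidualizedMatrix",
    "residualize",
    "standardize_columns",
    "max_abs_corr",
    "corr_to_pvalue",
    "nominal_pass",
]


@dataclass
class ResidualizedMatrix:
    """Least-squares residuals of a matrix on [intercept | covariates].

    ``df_resid = n - K - 2`` is the degrees of freedom available to the SNP
    t-test after spending one on the intercept, K on covariates and one on
    the SNP itself.
    """

    values: np.ndarray
    df_resid: int


def _design(X: CovariateMatrix, n: int) -> np.ndarray:
    return np.column_stack([np.ones(n), X.values]) if X.n_covariates else np.ones((n, 1))


def residualize(M: np.ndarray, X: CovariateMatrix) -> ResidualizedMatrix:
    """Project out the intercept and covariates from each column of ``M``."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n = M.shape[0]
    if X.values.shape[0] != n:
        raise ValueError("covariate matrix and target matrix disagree on n")
    D = _design(X, n)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify offending columns for the error message
        bad = []
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) < j + 1:
                bad.append(X.covariate_ids[j - 1] if X.covariate_ids else str(j - 1))
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    resid = M - D @ coef
    df = n - X.n_covariates - 2
    if df < 1:
        raise ValueError(f"too few samples: df = n - K - 2 = {df} < 1")
    return ResidualizedMatrix(resid, df)


def standardize_columns(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale columns to unit population (1/n) variance; flag zero-variance ones.

    Returns (standardized matrix, boolean mask of nondegenerate columns).
    Degenerate columns are left as zeros. Columns are assumed centered
    (residualization against an intercept guarantees this).
    """
    n = R.shape[0]
    norms = np.sqrt(np.einsum("ij,ij->j", R, R) / n)
    ok = norms > 1e-12 * max(1.0, float(np.abs(R).max(initial=0.0)))
    out = np.zeros_like(R)
    out[:, ok] = R[:, ok] / norms[ok]
    return out, ok


def max_abs_corr(expr_resid: np.ndarray, geno_std: np.ndarray) -> tuple[float, int]:
    """Maximum |Pearson correlation| between one residualized expression
    vector and the (standardized) residualized SNP columns.

    Returns ``(t, lead_index)``; ties resolve to the first SNP. ``geno_std``
    must already have unit-variance columns (zero-variance ones dropped).
    """
    n = expr_resid.shape[0]
    nrm = float(np.sqrt(expr_resid @ expr_resid / n))
    if nrm < 1e-14:
        raise ValueError("all-zero expression residual; gene cannot be tested")
    r = np.abs(geno_std.T @ (expr_resid / nrm)) / n
    lead = int(np.argmax(r))
    return float(min(r[lead], 1.0)), lead


def corr_to_pvalue(r, n: int, K: int):
    """Two-sided P value of the SNP coefficient implied by partial corr ``r``.

    Vectorized over ``r``. ``|r| = 1`` maps to 0 exactly.
    """
    df = n - K - 2
    if df < 1:
        raise ValueError(f"df = n - K - 2 = {df} < 1")
    r = np.asarray(r, dtype=float)
    a = np.abs(r)
    if np.any(a > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    a = np.minimum(a, 1.0)
    with np.errstate(divide="ignore"):
        t = a * np.sqrt(df) / np.sqrt(1.0 - a**2)
    p = np.where(a >= 1.0, 0.0, 2.0 * stats.t.sf(t, df))
    return float(p) if p.ndim == 0 else p


def nominal_pass(
    expr: ExpressionMatrix,
    blocks: list[CisGenotypeBlock],
    X: CovariateMatrix,
) -> pd.DataFrame:
    """All gene-SNP pair partial correlations and P values (Matrix eQTL-style).

    Returns a DataFrame with columns gene_id, snp_id, r, pvalue.
    """
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    expr_res = residualize(expr.values, X)
    rows: list[pd.DataFrame] = []
    n = expr.n_samples
    for block in blocks:
        if block.n_snps == 0:
            continue
        geno_res = residualize(block.dosages, X)
        geno_std, ok = standardize_columns(geno_res.values)
        if not ok.any():
            continue
        y = expr_res.values[:, gene_pos[block.gene_id]]
        nrm = float(np.sqrt(y @ y / n))
        if nrm < 1e-14:
            warnings.warn(f"gene {block.gene_id} has zero residual variance; skipped")
            continue
        r = (geno_std[:, ok].T @ (y / nrm)) / n
        r = np.clip(r, -1.0, 1.0)
        snp_ids = [s for s, keep in zip(block.snp_ids, ok) if keep]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": block.gene_id,
                    "snp_id": snp_ids,
                    "r": r,
                    "pvalue": corr_to_pvalue(r, n, X.n_covariates),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "snp_id", "r", "pvalue"])
    return pd.concat(rows, ignore_index=True)
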