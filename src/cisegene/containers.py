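"""Core typed containers shared by all pipeline stages.

The eGene identification problem takes three sample-aligned inputs: an
``n x p`` fully processed expression matrix ``Y``, per-gene ``n x q_j``
local-SNP dosage matrices ``S_j``, and an ``n x K`` covariate matrix ``X``.
A gene is an eGene if at least one local SNP has a nonzero coefficient in
the linear model of its expression on ``[1, S_j, X]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CisGenotypeBlock",
    "CovariateMatrix",
    "MethodConfig",
    "GeneStat",
    "EGeneResult",
    "align_samples",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Samples-by-genes expression with per-gene TSS coordinates.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Fully processed expression; no missing values allowed.
    sample_ids, gene_ids : lists of unique identifiers.
    tss : list of (chromosome, position)
        1-based transcription start site per gene.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    tss: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples x genes)")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 gene")
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError(
                f"id/shape mismatch: values {self.values.shape}, "
                f"{len(self.sample_ids)} sample_ids, {len(self.gene_ids)} gene_ids"
            )
        if len(self.tss) != p:
            raise ValueError("need one TSS per gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression contains missing/non-finite values")
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.gene_ids, "gene_id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            self.sample_ids,
            [self.gene_ids[i] for i in index],
            [self.tss[i] for i in index],
        )

    def subset_samples(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index, :],
            [self.sample_ids[i] for i in index],
            self.gene_ids,
            self.tss,
        )


@dataclass
class CisGenotypeBlock:
    """Dosage matrix of local SNPs for one gene (n samples x q_j SNPs)."""

    gene_id: str
    dosages: np.ndarray
    snp_ids: list[str]
    snp_positions: list[int]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        q = self.dosages.shape[1]
        if len(self.snp_ids) != q or len(self.snp_positions) != q:
            raise ValueError("snp_ids/snp_positions length must equal number of SNP columns")
        if q and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, index: np.ndarray) -> "CisGenotypeBlock":
        index = np.asarray(index, dtype=int)
        return CisGenotypeBlock(
            self.gene_id,
            self.dosages[:, index],
            [self.snp_ids[i] for i in index],
            [self.snp_positions[i] for i in index],
        )


@dataclass
class CovariateMatrix:
    """Known plus inferred covariates, samples x K. May have K = 0."""

    values: np.ndarray
    covariate_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariates must be 2-D (samples x covariates)")
        if len(self.covariate_ids) != self.values.shape[1]:
            raise ValueError("covariate_ids length must equal number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates contain missing/non-finite values")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @staticmethod
    def empty(n: int) -> "CovariateMatrix":
        return CovariateMatrix(np.empty((n, 0)), [])


@dataclass
class MethodConfig:
    """Tuning parameters for the eGene callers.

    ``B`` defaults to 1000 for the standard (permute-then-residualize,
    proportions P value) variant; the contrastive variant is designed for
    ``B = 1`` or ``20 <= B <= 100`` and warns outside that range.
    """

    variant: Literal["standard", "clipper"] = "standard"
    B: int | None = None
    target_fdr: float = 0.05
    cis_window_bp: int = 1_000_000
    maf_min: float = 0.01
    ma_samples_min: int = 10
    seed: int = 0
    fdr_procedure: Literal["storey", "bh", "by"] = "storey"

    def __post_init__(self) -> None:
        if self.variant not in ("standard", "clipper"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.B is None:
            self.B = 1000 if self.variant == "standard" else 1
        if self.B < 1:
            raise ValueError("B must be a positive integer")
        if not 0 < self.target_fdr < 1:
            raise ValueError("target_fdr must be in (0, 1)")
        if self.variant == "clipper" and not (self.B == 1 or 20 <= self.B <= 100):
            warnings.warn(
                f"B={self.B} outside the recommended range for the clipper "
                "variant (1, or 20-100)",
                stacklevel=2,
            )
        if self.variant == "standard" and self.B < 100:
            warnings.warn(
                f"B={self.B} permutations is low for the standard variant; "
                ">=100 recommended",
                stacklevel=2,
            )


@dataclass
class GeneStat:
    """Per-gene experimental and background association scores.

    ``t_exp`` is the maximum absolute partial correlation between the gene's
    expression and its local SNP dosages on observed data; ``t_bg[b]`` is
    the same statistic on the b-th permuted copy.
    """

    gene_id: str
    t_exp: float
    t_bg: np.ndarray
    lead_snp: str
    q_j: int

    def __post_init__(self) -> None:
        self.t_bg = np.asarray(self.t_bg, dtype=float)
        if not 0.0 <= self.t_exp <= 1.0 + 1e-12:
            raise ValueError(f"t_exp out of [0,1]: {self.t_exp}")
        if self.t_bg.size and (self.t_bg.min() < 0 or self.t_bg.max() > 1 + 1e-12):
            raise ValueError("background scores out of [0,1]")


@dataclass
class EGeneResult:
    """Gene-level outcome: P value or contrast score, q value, eGene call."""

    gene_id: str
    q_value: float
    is_egene: bool
    method: str
    lead_snp: str = ""
    statistic: float = np.nan
    gene_pvalue: float | None = None
    contrast_score: float | None = None


def align_samples(
    expr: ExpressionMatrix,
    covariates: CovariateMatrix | None,
    covariate_sample_ids: list[str] | None = None,
    genotype_sample_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, CovariateMatrix, np.ndarray | None]:
    """Match samples across matrices by id intersection.

    Expression-matrix order is preserved. Returns the aligned expression and
    covariates plus the integer index into the genotype sample axis (or
    ``None`` if no genotype ids were supplied).
    """
    keep = list(range(expr.n_samples))
    if covariate_sample_ids is not None:
        cov_set = set(covariate_sample_ids)
        keep = [i for i in keep if expr.sample_ids[i] in cov_set]
    geno_index = None
    if genotype_sample_ids is not None:
        geno_pos = {s: i for i, s in enumerate(genotype_sample_ids)}
        keep = [i for i in keep if expr.sample_ids[i] in geno_pos]
    if not keep:
        raise ValueError("empty sample intersection between input matrices")
    expr_out = expr.subset_samples(np.asarray(keep)) if len(keep) < expr.n_samples else expr
    if covariates is None:
        cov_out = CovariateMatrix.empty(expr_out.n_samples)
    elif covariate_sample_ids is not None:
        cov_pos = {s: i for i, s in enumerate(covariate_sample_ids)}
        rows = [cov_pos[s] for s in expr_out.sample_ids]
        cov_out = CovariateMatrix(covariates.values[rows, :], covariates.covariate_ids)
    else:
        if covariates.values.shape[0] != expr_out.n_samples:
            raise ValueError(
                "covariate matrix has a different number of samples than the "
                "expression matrix and no sample ids to match on"
            )
        cov_out = covariates
    if genotype_sample_ids is not None:
        geno_index = np.asarray([geno_pos[s] for s in expr_out.sample_ids])
    return expr_out, cov_out, geno_index
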