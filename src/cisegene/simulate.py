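"""Synthetic expression/genotype/covariate generator with ground truth.

Emulates the generative model behind the eGene problem: for gene j,

    Y[, j] = 1 b0 + S_j b1 + X b2 + noise,

where a stated fraction of eGenes carry a sparse nonzero b1. Genotypes are
drawn per gene as dosages {0,1,2} by thresholding a latent Gaussian copula
at Hardy-Weinberg quantiles, with haplotype-block LD (strong AR(1)
correlation within blocks of consecutive SNPs, independence across blocks,
as across recombination hotspots) and minor allele frequencies uniform on
a range. Covariates are standard normal and all treated as known.

The genotype component of each eGene is taken orthogonal to the covariate
span, so the analysis-side partial correlation recovers it exactly. Two
effect-size conventions are supported: ``expected`` (default) draws causal
coefficients from a Gaussian prior scaled so the per-gene realized
genotype variance fraction averages PVEGenotype across eGenes, giving the
chi-square spread of effect strengths that makes power comparisons
informative; ``realized`` rescales each gene so its in-sample fraction
equals PVEGenotype exactly (useful for calibration checks). Covariate and
noise components are scaled to their exact in-sample fractions in both
modes.

Defaults mirror a bulk-tissue-sized study: n=838 individuals, p=1000
genes, 20 covariates explaining half the variance, and a weak cis effect
(2% of variance) in 20% of genes — a regime where caller power
differences are visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .containers import CisGenotypeBlock, CovariateMatrix, ExpressionMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "evaluate_calls"]

_GENE_SPACING = 3_000_000  # > 2x the cis window, so gene windows never overlap


@dataclass
class SimConfig:
    n: int = 838
    p: int = 1000
    K_true: int = 20
    pve_genotype: float = 0.02
    pve_covariates: float = 0.5
    egene_fraction: float = 0.2
    snps_per_gene: int = 500
    causal_snps_per_egene: int = 1
    ld_rho: float = 0.99
    ld_block_snps: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_scaling: str = "expected"  # "expected" | "realized"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pve_genotype < 1 or not 0 <= self.pve_covariates < 1:
            raise ValueError("variance fractions must lie in [0, 1)")
        if self.pve_genotype + self.pve_covariates >= 1:
            raise ValueError("pve_genotype + pve_covariates must be < 1")
        if not 0 < self.egene_fraction < 1:
            raise ValueError("egene_fraction must be in (0, 1)")
        if self.effect_scaling not in ("expected", "realized"):
            raise ValueError("effect_scaling must be 'expected' or 'realized'")


@dataclass
class SimTruth:
    is_egene: np.ndarray                      # bool per gene
    causal_snps: dict[str, list[int]] = field(default_factory=dict)
    realized_pves: np.ndarray | None = None   # genotype variance fraction per gene


def _block_ld_dosages(
    rng: np.random.Generator,
    n: int,
    q: int,
    rho: float,
    block: int,
    mafs: np.ndarray,
) -> np.ndarray:
    """Dosages with haplotype-block LD.

    The latent Gaussian is AR(1) with coefficient ``rho`` inside consecutive
    blocks of ``block`` SNPs and independent across blocks (mimicking
    recombination hotspots), then thresholded at Hardy-Weinberg quantiles
    to give {0,1,2} with the requested minor allele frequencies.
    """
    z = rng.standard_normal((n, q))
    if q > 1 and rho > 0 and block > 1:
        latent = np.empty_like(z)
        for start in range(0, q, block):
            x = z[:, start : start + block].copy()
            x[:, 1:] *= np.sqrt(1 - rho**2)
            latent[:, start : start + block] = signal.lfilter(
                [1.0], [1.0, -rho], x, axis=1
            )
    else:
        latent = z
    p_hom_major = (1 - mafs) ** 2
    c0 = stats.norm.ppf(p_hom_major)
    c1 = stats.norm.ppf(p_hom_major + 2 * mafs * (1 - mafs))
    return (latent > c0).astype(float) + (latent > c1)


def _scaled(v: np.ndarray, target_var: float, n: int) -> np.ndarray:
    sd = np.sqrt(v @ v / n)
    if sd == 0:
        raise ZeroDivisionError
    return v * (np.sqrt(target_var) / sd)


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, list[CisGenotypeBlock], CovariateMatrix, SimTruth]:
    """One full data set: expression, per-gene cis dosage blocks, known
    covariates, and the eGene/causal-SNP ground truth."""
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n, config.p, config.snps_per_gene
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{j + 1:04d}" for j in range(p)]
    tss = [("chr1", 2_000_001 + j * _GENE_SPACING) for j in range(p)]

    X = rng.standard_normal((n, config.K_true))
    covariates = CovariateMatrix(X, [f"C{k + 1}" for k in range(config.K_true)])

    is_egene = np.zeros(p, dtype=bool)
    if config.pve_genotype > 0:  # a zero cis effect means no gene is an eGene
        n_egenes = int(round(p * config.egene_fraction))
        egene_idx = rng.choice(p, size=n_egenes, replace=False)
        is_egene[egene_idx] = True

    Y = np.empty((n, p))
    blocks: list[CisGenotypeBlock] = []
    truth = SimTruth(is_egene=is_egene, realized_pves=np.zeros(p))
    snp_offsets = np.linspace(-900_000, 900_000, q).astype(int)

    # orthonormal basis of [intercept | covariates] for exact decomposition
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), X]))

    def perp_cov(v: np.ndarray) -> np.ndarray:
        return v - Q @ (Q.T @ v)

    for j in range(p):
        # SNPs in strong LD ride the same haplotypes, hence share their
        # allele frequency: draw one MAF per LD block
        n_blocks = -(-q // config.ld_block_snps)
        mafs = np.repeat(
            rng.uniform(*config.maf_range, size=n_blocks), config.ld_block_snps
        )[:q]
        S = _block_ld_dosages(rng, n, q, config.ld_rho, config.ld_block_snps, mafs)
        blocks.append(
            CisGenotypeBlock(
                gene_id=gene_ids[j],
                dosages=S,
                snp_ids=[f"{gene_ids[j]}_snp{k + 1}" for k in range(q)],
                snp_positions=[tss[j][1] + int(o) for o in snp_offsets],
            )
        )
        y = np.zeros(n)
        g = None
        pve_noise = 1.0 - config.pve_covariates
        if is_egene[j]:
            causal = list(rng.choice(q, size=config.causal_snps_per_egene, replace=False))
            for _ in range(20):  # resample degenerate causal SNP sets
                beta1 = rng.standard_normal(len(causal))
                Sp = perp_cov(S[:, causal] @ beta1)  # cis effect beyond covariates
                var_g = Sp @ Sp / n
                if var_g > 1e-10:
                    break
                warnings.warn(f"zero-variance causal SNP for {gene_ids[j]}; resampling")
                causal = list(rng.choice(q, size=config.causal_snps_per_egene, replace=False))
            if config.effect_scaling == "realized":
                # exact in-sample genotype variance fraction
                g = Sp * np.sqrt(config.pve_genotype / var_g)
            else:
                # effect size drawn from a prior: realized per-gene PVE varies
                # around pve_genotype (chi-square across eGenes), as when
                # coefficients are sampled rather than calibrated per gene
                Scols = perp_cov(S[:, causal])
                expected_var = np.einsum("ij,ij->", Scols, Scols) / n / len(causal)
                g = Sp * np.sqrt(config.pve_genotype / (len(causal) * expected_var))
            truth.causal_snps[gene_ids[j]] = causal
            y = y + g
            gvar = g @ g / n
            pve_noise -= config.pve_genotype
        if config.K_true and config.pve_covariates > 0:
            beta2 = rng.standard_normal(config.K_true)
            c0 = X @ beta2
            y = y + _scaled(c0 - c0.mean(), config.pve_covariates, n)
        eps = perp_cov(rng.standard_normal(n))
        if g is not None:
            eps = eps - (g @ eps) / (g @ g) * g
        y = y + _scaled(eps, max(pve_noise, 1e-12), n)
        if is_egene[j]:
            truth.realized_pves[j] = gvar / (y @ y / n)  # components are orthogonal
        Y[:, j] = y

    expr = ExpressionMatrix(Y, sample_ids, gene_ids, tss)
    return expr, blocks, covariates, truth


def evaluate_calls(truth: SimTruth, calls: np.ndarray) -> tuple[float, float]:
    """False discovery proportion and power of a boolean call vector."""
    calls = np.asarray(calls, dtype=bool)
    if calls.shape != truth.is_egene.shape:
        raise ValueError("calls and truth are not aligned")
    discoveries = int(calls.sum())
    false_disc = int(np.sum(calls & ~truth.is_egene))
    n_egenes = int(truth.is_egene.sum())
    fdp = false_disc / max(1, discoveries)
    power = np.sum(calls & truth.is_egene) / n_egenes if n_egenes else 0.0
    return float(fdp), float(power)
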