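"""Readers/writers, SNP and gene filters, cis-window extraction, pseudobulk.

Formats (all tab-separated UTF-8):

* expression BED — ``#chr  start  end  gene_id  <sample...>``; the BED
  interval is 0-based half-open and the TSS is taken as ``start + 1``
  (the conventional dialect puts the TSS at the start coordinate).
* dosage TSV — ``snp_id  chrom  pos  <sample...>`` with dosages in [0,2];
  VCF (via cyvcf2) is accepted as an alternative, using the DS FORMAT
  field when present and the GT allele count otherwise.
* covariate TSV — covariate x sample or sample x covariate; orientation
  is auto-detected by matching identifiers against the expression samples.
* results TSV — one row per gene, ordered by gene_id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CisGenotypeBlock, CovariateMatrix, EGeneResult, ExpressionMatrix

__all__ = [
    "read_expression_bed",
    "write_expression_bed",
    "GenotypeSource",
    "read_covariates_tsv",
    "extract_cis_block",
    "filter_snps",
    "CellCountMatrix",
    "pseudobulk",
    "filter_genes_nonzero",
    "write_results_tsv",
    "read_results_tsv",
]


def read_expression_bed(path) -> ExpressionMatrix:
    """Read a FastQTL-style expression BED into samples x genes."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 5:
        raise ValueError("expression BED needs chrom/start/end/gene_id plus >=1 sample")
    chrom, start, gene_id = df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 3].astype(str)
    dup = gene_id[gene_id.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id in expression BED: {dup.iloc[0]!r}")
    values = df.iloc[:, 4:]
    for col in values.columns:
        bad = pd.to_numeric(values[col], errors="coerce")
        if bad.isna().any():
            row = int(np.argmax(bad.isna().to_numpy()))
            raise ValueError(
                f"non-numeric expression value at gene {gene_id.iloc[row]!r}, sample {col!r}"
            )
    tss = [(c, int(s) + 1) for c, s in zip(chrom, start)]  # BED start is 0-based
    return ExpressionMatrix(
        values.to_numpy(dtype=float).T,
        [str(c) for c in values.columns],
        list(gene_id),
        tss,
    )


def write_expression_bed(expr: ExpressionMatrix, path) -> None:
    meta = pd.DataFrame(
        {
            "#chr": [c for c, _ in expr.tss],
            "start": [pos - 1 for _, pos in expr.tss],
            "end": [pos for _, pos in expr.tss],
            "gene_id": expr.gene_ids,
        }
    )
    values = pd.DataFrame(expr.values.T, columns=expr.sample_ids)
    pd.concat([meta, values], axis=1).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeSource:
    """In-memory dosage table indexed by SNP position."""

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray  # snps x samples
    sample_ids: list[str]

    @staticmethod
    def from_dosage_tsv(path) -> "GenotypeSource":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        return GenotypeSource(
            snp_ids=list(df.iloc[:, 0].astype(str)),
            chrom=df.iloc[:, 1].astype(str).to_numpy(),
            pos=df.iloc[:, 2].to_numpy(dtype=int),
            dosages=df.iloc[:, 3:].to_numpy(dtype=float),
            sample_ids=[str(c) for c in df.columns[3:]],
        )

    @staticmethod
    def from_vcf(path) -> "GenotypeSource":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, poss, rows = [], [], [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                warnings.warn(f"skipping multiallelic record at {rec.CHROM}:{rec.POS}")
                continue
            if "DS" in (rec.FORMAT or ""):
                d = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
            else:
                gt = np.asarray(rec.gt_types, dtype=float)  # 0,1,3->dosage; 2=unknown
                d = np.where(gt == 3, 2.0, gt)
                d[np.asarray(rec.gt_types) == 2] = np.nan
            if np.isnan(d).any():
                warnings.warn(
                    f"mean-imputing missing genotypes at {rec.CHROM}:{rec.POS}"
                )
                d = np.where(np.isnan(d), np.nanmean(d), d)
            ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            rows.append(np.clip(d, 0, 2))
        return GenotypeSource(
            ids, np.asarray(chroms), np.asarray(poss, dtype=int), np.asarray(rows), samples
        )

    def write_dosage_tsv(self, path) -> None:
        meta = pd.DataFrame({"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos})
        values = pd.DataFrame(self.dosages, columns=self.sample_ids)
        pd.concat([meta, values], axis=1).to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path, sample_ids: list[str]) -> tuple[CovariateMatrix, list[str]]:
    """Read a covariate TSV in either orientation.

    Orientation is resolved by matching identifiers against ``sample_ids``;
    returns the covariates as samples x K plus the row sample ids (callers
    align them to the expression matrix with
    :func:`cisegene.containers.align_samples`).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ss = set(sample_ids)
    in_cols = sum(str(c) in ss for c in df.columns)
    in_rows = sum(str(r) in ss for r in df.index)
    if in_cols == 0 and in_rows == 0:
        raise ValueError("covariate file shares no sample ids with the expression matrix")
    if in_cols > in_rows:  # covariate x sample -> transpose
        df = df.T
    return (
        CovariateMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns]),
        [str(r) for r in df.index],
    )


def extract_cis_block(
    gene_id: str,
    tss: tuple[str, int],
    source: GenotypeSource,
    window: int = 1_000_000,
) -> CisGenotypeBlock:
    """All biallelic SNPs with |pos - TSS| <= window (closed interval)."""
    chrom, pos = tss
    if pos is None or pos < 1:
        raise ValueError(f"gene {gene_id!r} has no valid TSS")
    mask = (source.chrom == chrom) & (np.abs(source.pos - pos) <= window)
    idx = np.flatnonzero(mask)
    return CisGenotypeBlock(
        gene_id=gene_id,
        dosages=source.dosages[idx, :].T,
        snp_ids=[source.snp_ids[i] for i in idx],
        snp_positions=[int(source.pos[i]) for i in idx],
    )


def filter_snps(
    block: CisGenotypeBlock, maf_min: float = 0.01, ma_samples_min: int = 10
) -> CisGenotypeBlock:
    """Keep SNPs with folded MAF >= maf_min AND minor-allele sample count
    >= ma_samples_min. An individual carries the minor allele if its dosage
    of that allele is >= 0.5. Idempotent; preserves SNP order."""
    if block.n_snps == 0:
        return block
    mean_alt = block.dosages.mean(axis=0) / 2.0
    maf = np.minimum(mean_alt, 1.0 - mean_alt)
    minor_dosage = np.where(mean_alt <= 0.5, block.dosages, 2.0 - block.dosages)
    ma_samples = (minor_dosage >= 0.5).sum(axis=0)
    keep = np.flatnonzero((maf >= maf_min) & (ma_samples >= ma_samples_min))
    return block.subset_snps(keep)


@dataclass
class CellCountMatrix:
    """Gene-by-cell UMI counts with per-cell individual and type labels."""

    counts: np.ndarray  # genes x cells, nonnegative integers
    gene_ids: list[str]
    cell_to_individual: list[str]
    cell_to_type: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("every retained cell must have positive total count")


def pseudobulk(
    counts: CellCountMatrix,
    cell_type: str,
    tss: list[tuple[str, int]] | None = None,
    scale: float = 10_000.0,
) -> ExpressionMatrix:
    """Per-individual pseudobulk expression for one cell type.

    Each count is normalized as ``log(count / per-cell-total * scale + 1)``
    (natural log); the per gene-individual value is the mean over that
    individual's cells in the non-log space (exponentiate, subtract one).
    With one cell per individual this reduces to ``count/total * scale``
    exactly. Individuals without cells of the type are excluded with a
    warning. TSS coordinates are placeholders unless supplied.
    """
    sel = [i for i, t in enumerate(counts.cell_to_type) if t == cell_type]
    if not sel:
        raise ValueError(f"no cells of type {cell_type!r}")
    sub = counts.counts[:, sel]
    totals = sub.sum(axis=0)
    norm = np.log(sub / totals * scale + 1.0)
    delogged = np.expm1(norm)  # == count/total * scale
    individuals = sorted(set(counts.cell_to_individual))
    indiv_of = [counts.cell_to_individual[i] for i in sel]
    rows, kept = [], []
    for person in individuals:
        cols = [i for i, s in enumerate(indiv_of) if s == person]
        if not cols:
            warnings.warn(f"individual {person!r} has no {cell_type!r} cells; excluded")
            continue
        rows.append(delogged[:, cols].mean(axis=1))
        kept.append(person)
    values = np.vstack(rows)
    if tss is None:
        tss = [("NA", 1)] * len(counts.gene_ids)
    return ExpressionMatrix(values, kept, list(counts.gene_ids), tss)


def filter_genes_nonzero(expr: ExpressionMatrix, min_fraction: float = 0.9) -> ExpressionMatrix:
    """Keep genes with nonzero expression in at least ``min_fraction`` of
    individuals (boundary inclusive). May return zero genes."""
    frac = (expr.values > 0).mean(axis=0)
    return expr.subset_genes(np.flatnonzero(frac >= min_fraction))


_RESULT_COLS = ["gene_id", "lead_snp", "statistic", "gene_pvalue", "contrast_score", "q_value", "is_egene"]


def write_results_tsv(results: list[EGeneResult], path) -> None:
    """One row per gene, ordered by gene_id; empty input gives header only."""
    rows = sorted(results, key=lambda r: r.gene_id)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "lead_snp": [r.lead_snp for r in rows],
            "statistic": [r.statistic for r in rows],
            "gene_pvalue": [r.gene_pvalue if r.gene_pvalue is not None else math.nan for r in rows],
            "contrast_score": [
                r.contrast_score if r.contrast_score is not None else math.nan for r in rows
            ],
            "q_value": [r.q_value for r in rows],
            "is_egene": ["true" if r.is_egene else "false" for r in rows],
        },
        columns=_RESULT_COLS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _RESULT_COLS:
        raise ValueError(f"unexpected results columns: {list(df.columns)}")
    if df["is_egene"].dtype != bool:
        df["is_egene"] = df["is_egene"].astype(str).str.lower() == "true"
    return df
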