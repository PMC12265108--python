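"""False discovery rate machinery.

Two routes to eGene calls at a target FDR:

* gene-level P values -> Benjamini-Hochberg, Benjamini-Yekutieli, or
  Storey q values (Storey with a fixed lambda = 0.5, the GTEx/FastQTL
  convention);
* contrast scores (experimental minus background association score) ->
  a P-value-free threshold in the style of Clipper (Ge et al. 2021):
  under the null the contrasts are roughly symmetric around zero, so the
  left tail estimates the false discoveries in the right tail,

      FDRhat(t) = (1 + #{j : C_j <= -t}) / max(1, #{j : C_j >= t}),

  and the cutoff is the smallest candidate t with FDRhat(t) <= target.
  Each gene also gets a q value, the minimal estimated FDR at which it
  would be called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GeneStat

__all__ = [
    "ContrastResult",
    "bh_adjust",
    "by_adjust",
    "storey_qvalue",
    "clipper_threshold",
    "call_egenes",
]


def _step_up(p: np.ndarray, multiplier: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * multiplier * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("P values must lie in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return _step_up(p, 1.0)


def by_adjust(p) -> np.ndarray:
    """Benjamini-Yekutieli: BH inflated by the harmonic number H_m."""
    p = _check_p(p)
    if p.size == 0:
        return p
    harmonic = np.sum(1.0 / np.arange(1, p.size + 1))
    return _step_up(p, harmonic)


def storey_qvalue(p, lam: float = 0.5) -> np.ndarray:
    """Storey q values with pi0 estimated at a single lambda.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m)); q values are the BH
    step-up values scaled by pi0. pi0 = 0 is clamped to 1/m with a warning.
    """
    p = _check_p(p)
    if p.size == 0:
        return p
    m = p.size
    pi0 = min(1.0, np.sum(p > lam) / ((1.0 - lam) * m))
    if pi0 == 0.0:
        warnings.warn("all P values <= lambda; clamping pi0 to 1/m")
        pi0 = 1.0 / m
    return _step_up(p, pi0)


@dataclass
class ContrastResult:
    """Contrast scores with their q values and the discovery cutoff."""

    gene_ids: list[str]
    contrast_scores: np.ndarray
    q_values: np.ndarray
    cutoff: float


def contrast_scores_from_stats(stats_list: list[GeneStat]) -> np.ndarray:
    """C_j = T_exp,j - max_b T_bg,j,b (reduces to T_exp - T_bg for B = 1)."""
    return np.asarray([s.t_exp - float(np.max(s.t_bg)) for s in stats_list])


def clipper_threshold(stats_list: list[GeneStat], target_fdr: float) -> ContrastResult:
    """Contrast-score thresholding with per-gene q values.

    All genes must share the same number of background scores B. Ties at
    the cutoff are discovered (>=). An all-negative contrast vector is a
    valid zero-discovery outcome.
    """
    if not stats_list:
        return ContrastResult([], np.empty(0), np.empty(0), np.inf)
    B = {s.t_bg.size for s in stats_list}
    if len(B) != 1:
        raise ValueError(f"genes disagree on B: {sorted(B)}")
    C = contrast_scores_from_stats(stats_list)
    q = contrast_qvalues(C)
    candidates = np.unique(np.abs(C))
    candidates = candidates[candidates > 0]
    cutoff = np.inf
    for t in candidates:  # increasing
        fdr_hat = (1 + np.sum(C <= -t)) / max(1, int(np.sum(C >= t)))
        if fdr_hat <= target_fdr:
            cutoff = float(t)
            break
    return ContrastResult([s.gene_id for s in stats_list], C, q, cutoff)


def contrast_qvalues(C: np.ndarray) -> np.ndarray:
    """q_j = min over candidate thresholds t <= C_j of FDRhat(t), in [0, 1].

    Genes with nonpositive contrasts (no admissible threshold) get q = 1.
    """
    C = np.asarray(C, dtype=float)
    candidates = np.unique(np.abs(C))
    candidates = candidates[candidates > 0]
    if candidates.size == 0:
        return np.ones_like(C)
    # FDRhat over the (sorted increasing) candidate grid
    n_neg = np.array([np.sum(C <= -t) for t in candidates])
    n_pos = np.array([np.sum(C >= t) for t in candidates])
    fdr_hat = (1 + n_neg) / np.maximum(1, n_pos)
    # min over t <= C_j  ==  running minimum from the left up to C_j
    running_min = np.minimum.accumulate(np.minimum(fdr_hat, 1.0))
    q = np.ones_like(C)
    idx = np.searchsorted(candidates, C, side="right") - 1
    pos = C > 0
    q[pos] = running_min[idx[pos]]
    return q


def call_egenes(q, target_fdr: float) -> np.ndarray:
    """eGene calls: q value at or below the target FDR."""
    q = np.asarray(q, dtype=float)
    return q <= target_fdr
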