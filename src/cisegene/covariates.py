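"""Choosing the number of inferred expression-PC covariates.

Two selectors are provided: the Buja-Eyuboglu (BE) permutation test
(parallel analysis — keep leading PCs whose variance explained beats the
permutation null, stopping at the first failure) and the elbow of the
scree curve (maximum perpendicular distance from the chord joining its
endpoints). BE behaves well on bulk-sized matrices but can overshoot on
pseudobulk single-cell matrices, where the elbow is the safer default.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix

__all__ = ["expression_pcs", "variance_explained", "choose_k_be", "choose_k_elbow", "elbow_index"]


def _standardized(expr: ExpressionMatrix) -> np.ndarray:
    """Column-standardized expression with constant genes dropped."""
    Y = expr.values
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    keep = sd > 0
    return (Y[:, keep] - mu[keep]) / sd[keep]


def expression_pcs(expr: ExpressionMatrix, k: int) -> np.ndarray:
    """Top-k principal component scores of the standardized expression.

    Sign convention: the largest-magnitude loading of each PC is positive.
    """
    Z = _standardized(expr)
    if k > min(Z.shape):
        raise ValueError(f"k={k} exceeds min(n, p)={min(Z.shape)}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    scores = U * S * flip
    return scores[:, :k]


def variance_explained(Z: np.ndarray) -> np.ndarray:
    """Fraction of total variance carried by each PC (descending)."""
    s = np.linalg.svd(Z, compute_uv=False)
    lam = s**2
    return lam / lam.sum()


def choose_k_be(
    expr: ExpressionMatrix,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> int:
    """Parallel-analysis PC count: permute each gene column independently
    ``n_perm`` times and keep leading PCs whose observed variance explained
    exceeds the (1 - alpha) permutation quantile for that PC index,
    stopping at the first failure."""
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    Z = _standardized(expr)
    n = Z.shape[0]
    obs = variance_explained(Z)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    for t in range(n_perm):
        perm = np.empty_like(Z)
        for j in range(Z.shape[1]):
            perm[:, j] = Z[rng.permutation(n), j]
        null[t] = variance_explained(perm)
    thresh = np.quantile(null, 1 - alpha, axis=0)
    k = 0
    for i in range(obs.size):
        if obs[i] > thresh[i]:
            k += 1
        else:
            break
    return k


def elbow_index(v: np.ndarray) -> int:
    """Index (1-based) of the point on a descending scree curve with the
    maximum perpendicular distance from the chord joining its endpoints.
    Invariant to rescaling the curve's values. Fewer than 3 points -> 1."""
    v = np.asarray(v, dtype=float)
    m = v.size
    if m < 3:
        return 1
    x = np.arange(1, m + 1, dtype=float)
    dx, dy = m - 1.0, v[-1] - v[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - 1) - dx * (v - v[0])) / norm
    if dist.max() <= 1e-9 * (abs(dy) + abs(v).max()):  # curve is a straight line
        return 1
    return int(np.argmax(dist) + 1)


def choose_k_elbow(expr: ExpressionMatrix) -> int:
    """Scree elbow: PC index with maximum perpendicular distance from the
    chord joining the first and last points of the variance-explained curve."""
    return elbow_index(variance_explained(_standardized(expr)))
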