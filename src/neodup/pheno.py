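"""Phenotype analysis: Gaussian trait fits, rank-sum comparisons, PCA, PED.

A trait matrix holds one row per individual with a genotype label and seven
morphological traits (rosette major/minor axis, leaf count, main-bolt branch
count, side-bolt count, days to first open flower, main-bolt height).
Per-genotype trait effects are summarised by maximum-likelihood Gaussian
fits; genotypes are compared trait-by-trait with the two-sided Wilcoxon
rank-sum test.

The global phenotype view is a PCA on the *covariance* matrix of the
mean-centred traits (the R ``princomp`` convention — traits are not
standardised; pass ``scale=True`` for the correlation-matrix variant).
Each genotype is reduced to its centroid in (PC1, PC2) space, and the
phenotypic-effect distance between genotypes i and j is the Euclidean
distance of their centroids:

    PED(Gi, Gj)² = [PC1(Gi) − PC1(Gj)]² + [PC2(Gi) − PC2(Gj)]²

Genotypes grown in separate experiments must be analysed in separate PCA
spaces; PED is never compared across spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = [
    "rosette_major_mm",
    "rosette_minor_mm",
    "leaf_count",
    "main_bolt_branches",
    "side_bolts",
    "days_to_flower",
    "main_bolt_height_mm",
]


@dataclass
class TraitGaussian:
    mu: float
    sigma: float
    n: int
    degenerate: bool = False


def fit_gaussian(values) -> TraitGaussian:
    """Maximum-likelihood Gaussian fit: mean and population SD (divisor n)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least two finite values")
    sigma = float(vals.std(ddof=0))
    return TraitGaussian(float(vals.mean()), sigma, int(vals.size), degenerate=sigma == 0.0)


def compare_traits(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two trait samples.

    Exact enumeration when the smaller sample has ≤8 observations and there
    are no ties across the pooled sample; normal approximation (with tie
    correction and continuity) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class PCAResult:
    """Covariance-PCA loadings, scores, variance fractions, and centroids."""

    loadings: pd.DataFrame  # trait × component
    scores: pd.DataFrame  # individual × component, with genotype column
    variance_fraction: np.ndarray
    centroids: dict[str, tuple[float, float]] = field(default_factory=dict)


def run_pca(
    tm: pd.DataFrame,
    trait_columns: list[str] | None = None,
    genotype_col: str = "genotype",
    scale: bool = False,
) -> PCAResult:
    """PCA of a trait matrix; rows with any missing trait are dropped.

    Components are ordered by decreasing eigenvalue of the covariance matrix
    (divisor n, matching ``princomp``); the sign of each component is fixed
    so its largest-magnitude loading is positive.  Per-genotype (PC1, PC2)
    centroids are attached for PED computation.
    """
    traits = trait_columns or [c for c in TRAIT_COLUMNS if c in tm.columns]
    if not traits:
        traits = [c for c in tm.columns if c != genotype_col]
    if len(traits) < 2:
        raise ValueError("need at least two trait columns")
    data = tm[[genotype_col, *traits]].dropna()
    if len(data) < 3:
        raise ValueError("need at least three complete-case individuals")
    X = data[traits].to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardise a zero-variance trait")
        X = X / sd
    centred = X - X.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    rank = int(np.linalg.matrix_rank(cov))
    if rank < len(traits):
        warnings.warn(f"rank-deficient trait matrix: {rank} informative components")
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    scores = centred @ eigvec
    comp_names = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=traits, columns=comp_names)
    scores_df = pd.DataFrame(scores, columns=comp_names, index=data.index)
    scores_df.insert(0, genotype_col, data[genotype_col].to_numpy())
    total = eigval.sum()
    var_frac = eigval / total if total > 0 else eigval
    centroids = {
        g: (float(sub["PC1"].mean()), float(sub["PC2"].mean()))
        for g, sub in scores_df.groupby(genotype_col)
    }
    return PCAResult(loadings, scores_df, var_frac, centroids)


def ped(pca: PCAResult, gi: str, gj: str) -> float:
    """Phenotypic-effect distance between two genotype centroids in PC1/PC2."""
    for g in (gi, gj):
        if g not in pca.centroids:
            raise KeyError(f"genotype {g!r} has no scored individuals")
    (x1, y1), (x2, y2) = pca.centroids[gi], pca.centroids[gj]
    return float(np.hypot(x1 - x2, y1 - y2))


def ped_matrix(pca: PCAResult) -> pd.DataFrame:
    """Symmetric matrix of PED values over all genotype pairs."""
    genos = sorted(pca.centroids)
    mat = pd.DataFrame(0.0, index=genos, columns=genos)
    for i, gi in enumerate(genos):
        for gj in genos[i + 1 :]:
            d = ped(pca, gi, gj)
            mat.loc[gi, gj] = mat.loc[gj, gi] = d
    return mat
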