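"""Descriptive layer: log transform, PCA, Spearman clustering, ddCt."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = [
    "PCAResult",
    "SampleClustering",
    "log_transform",
    "pca",
    "cluster_samples",
    "ddct",
    "linkage_to_newick",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fractions, non-increasing, sum 1

    def __post_init__(self) -> None:
        v = np.asarray(self.variance_explained, dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("variance fractions must lie in [0, 1]")
        if np.any(np.diff(v) > 1e-9):
            raise ValidationError("variance fractions must be non-increasing")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError("variance fractions must sum to 1")


@dataclass
class SampleClustering:
    correlation: pd.DataFrame  # Spearman rho, samples x samples
    linkage: np.ndarray  # scipy linkage matrix on 1 - rho
    newick: str


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount); input must be non-negative."""
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("log transform requires non-negative input")
    return pd.DataFrame(np.log2(x + pseudocount), index=matrix.index, columns=matrix.columns)


def pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA of a samples x features matrix (columns centered, not scaled).

    Scores are the centered data projected on right singular vectors;
    variance fractions come from the singular values and sum to one over all
    components of the centered matrix.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValidationError("matrix has no variance across samples")
    frac = var / total
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
        variance_explained=frac,
    )


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    # rank each column (average ties) then Pearson
    ranks = np.column_stack([rankdata(x[:, j]) for j in range(x.shape[1])])
    return np.corrcoef(ranks, rowvar=False)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def cluster_samples(matrix: pd.DataFrame, method: str = "complete") -> SampleClustering:
    """Pairwise Spearman rho between samples (columns) and a hierarchical
    clustering of 1 - rho distances."""
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    x = matrix.to_numpy(dtype=float)
    stds = x.std(axis=0)
    constant = np.where(stds == 0)[0]
    if constant.size:
        names = [str(matrix.columns[j]) for j in constant]
        raise ValidationError(
            f"constant samples have undefined rank correlation: {names}"
        )
    rho = _spearman_matrix(x)
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=matrix.columns, columns=matrix.columns)
    dist = 1.0 - rho
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method=method)
    newick = linkage_to_newick(link, [str(c) for c in matrix.columns])
    return SampleClustering(correlation=corr, linkage=link, newick=newick)


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression 2**-ddCt versus a reference gene and calibrator."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValidationError("Ct values must be finite")
    delta_sample = ct_target_sample - ct_ref_sample
    delta_calibrator = ct_target_calibrator - ct_ref_calibrator
    return float(2.0 ** -(delta_sample - delta_calibrator))
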