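"""Variable-gene selection, complete-linkage clustering and PCA.

These are the profile-level views of a knockdown/rescue experiment: the most
variable genes across samples drive the heatmap, agglomerative clustering
with complete linkage groups genes or samples, and PCA places each sample's
transcriptional profile in a low-dimensional plane where a dead construct
lands near the knockdown control and a full rescue near the unperturbed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "top_variable_genes",
    "hierarchical_cluster",
    "linkage_to_newick",
    "pca_scores",
]


def top_variable_genes(expr: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` genes with the largest across-sample variance.

    Ties are broken lexicographically by gene id; ``n <= 0`` returns an
    empty list.
    """
    if n <= 0:
        return []
    if n > expr.shape[0]:
        raise ValueError("n exceeds the number of genes")
    var = expr.var(axis=1, ddof=1)
    order = sorted(zip(-var.to_numpy(), expr.index.astype(str)))
    return [g for _, g in order[:n]]


def hierarchical_cluster(expr: pd.DataFrame, linkage: str = "complete",
                         metric: str = "euclidean",
                         standardize: bool = True) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the rows of ``expr``.

    With complete linkage the distance between clusters is the maximum
    pairwise distance, so merge heights are non-decreasing.  Rows are
    z-scored first by default (``correlation`` may be passed as ``metric``
    instead).  Returns the SciPy linkage matrix and the row labels in input
    order; ties are resolved by SciPy's deterministic nearest-neighbor chain
    order.
    """
    if expr.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    X = expr.to_numpy(dtype=float)
    if standardize and metric == "euclidean":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    d = pdist(X, metric=metric)
    if np.isnan(d).any():
        raise ValueError("NA distances; check for constant rows under correlation")
    Z = hierarchy.linkage(d, method=linkage)
    return Z, [str(g) for g in expr.index]


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick tree (heights as branch lengths)."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def pca_scores(expr: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component coordinates of expression profiles.

    Samples are the observations, genes the features; each gene is centered
    across samples and scores come from the singular value decomposition.
    The sign of each component is fixed so the loading with the largest
    magnitude is positive.  A zero-variance matrix yields all-zero scores
    and NaN variance fractions.

    Returns
    -------
    scores : DataFrame, samples x PC1..PCk
    variance_fractions : ndarray, non-increasing, summing to <= 1
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    n_samples = X.shape[0]
    k = min(n_components, n_samples, X.shape[1])
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S ** 2).sum())
    if total <= 0:
        scores = np.zeros((n_samples, k))
        fractions = np.full(k, np.nan)
    else:
        # sign convention: largest-magnitude loading of each PC positive
        for i in range(len(S)):
            j = int(np.argmax(np.abs(Vt[i])))
            if Vt[i, j] < 0:
                Vt[i] *= -1.0
                U[:, i] *= -1.0
        scores = (U[:, :k] * S[:k])
        fractions = (S[:k] ** 2) / total
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(scores, index=expr.columns, columns=cols), fractions
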