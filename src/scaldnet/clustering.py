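"""PCA smoothing and k-means summarization of gene expression.

Gene profiles (genes as points, samples as dimensions) are first
denoised by reconstructing the expression matrix from its leading
principal components, then partitioned with a single run of Lloyd's
k-means initialized from k_init genes drawn uniformly without
replacement.  Clusters left empty at convergence are deleted, so the
final cluster count may be below k_init.  Cluster means are computed on
the *unsmoothed* (scaled) expression; smoothing only stabilizes the
centroid estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SizingError, ValidationError

MAX_ITER = 300


def pca_smooth(X: np.ndarray | pd.DataFrame, n_pcs: int = 10) -> np.ndarray:
    """Low-rank reconstruction of ``X`` from its first ``n_pcs`` PCs.

    PCA is taken over the rows (column-mean centring); the output has
    the same shape as the input, and reconstruction with n_pcs equal to
    the matrix rank is exact.
    """
    X = np.asarray(X, dtype=float)
    rank = int(np.linalg.matrix_rank(X))
    if n_pcs < 1 or n_pcs > rank:
        raise SizingError(f"n_pcs={n_pcs} outside 1..rank={rank}")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    return (U[:, :n_pcs] * s[:n_pcs]) @ Vt[:n_pcs] + mean


@dataclass
class ClusterModel:
    """k-means summary of gene expression profiles."""

    gene_ids: list[str]
    labels: np.ndarray  # gene -> cluster index, 0..K-1, empty clusters removed
    centroids: np.ndarray  # K x samples (in the smoothed profile space)
    k_init: int
    seed: int
    n_iter: int
    sse: float

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "cluster_id": self.labels}
        )

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.labels) if c == cluster_id]


def kmeans_summarize(
    X: np.ndarray | pd.DataFrame,
    gene_ids: list[str] | None = None,
    k_init: int = 100,
    seed: int = 0,
) -> ClusterModel:
    """Single-run Lloyd's k-means over gene profiles.

    Centroids start at ``k_init`` distinct gene points sampled without
    replacement.  Iteration stops when assignments are unchanged or
    after 300 rounds; within-cluster SSE is asserted non-increasing at
    every step.  Empty clusters are deleted after convergence and the
    remaining clusters relabelled consecutively.
    """
    if isinstance(X, pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(X.index)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 1:
        raise ValidationError("need at least one gene to cluster")
    if k_init < 1:
        raise ValidationError("k_init must be >= 1")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]

    rng = np.random.default_rng(seed)
    k = min(k_init, n)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()

    prev_labels = None
    prev_sse = np.inf
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1)
        sse = float(d2[np.arange(n), labels].sum())
        # Lloyd's algorithm is monotone in within-cluster SSE
        assert sse <= prev_sse + 1e-9 * max(abs(prev_sse), 1.0), (
            "k-means SSE increased"
        )
        prev_sse = sse
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        for c in range(k):
            mask = labels == c
            if mask.any():
                centroids[c] = X[mask].mean(axis=0)
            # empty clusters keep their centroid and are pruned at the end

    occupied = np.unique(labels)
    relabel = {old: new for new, old in enumerate(occupied)}
    labels = np.array([relabel[c] for c in labels])
    centroids = centroids[occupied]
    return ClusterModel(
        gene_ids=list(gene_ids),
        labels=labels,
        centroids=centroids,
        k_init=k_init,
        seed=seed,
        n_iter=n_iter,
        sse=prev_sse,
    )


def cluster_means(model: ClusterModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean profile per cluster (clusters x samples).

    ``expr`` is the genes x samples matrix the model's genes came from
    (scaled but unsmoothed).
    """
    missing = set(model.gene_ids) - set(expr.index)
    if missing:
        raise ValidationError(
            "cluster genes absent from expression matrix: "
            + ", ".join(sorted(missing)[:10])
        )
    X = expr.loc[model.gene_ids].to_numpy(dtype=float)
    K = model.n_clusters
    means = np.vstack(
        [X[model.labels == c].mean(axis=0) for c in range(K)]
    )
    return pd.DataFrame(
        means, index=pd.RangeIndex(K, name="cluster_id"), columns=expr.columns
    )
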