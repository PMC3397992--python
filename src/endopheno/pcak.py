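"""PCA-K baseline: SVD principal-component scores plus k-means.

The comparison method for subtype discovery: genes are centred, the matrix
is decomposed by SVD, samples are projected onto the leading right singular
directions, and the score matrix is clustered with standard k-means under
squared Euclidean distance.  The number of retained components equals the
cluster count so the comparison with rank-k NMF is dimension-fair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["pca_scores", "PCAKMeans", "PCAKMeansResults", "pca_k_cluster"]


def pca_scores(V, n_components: int) -> np.ndarray:
    """Samples x components PC score matrix of a genes x samples matrix.

    Each gene (row) is centred across samples; the scores are the
    projections of samples onto the top right singular directions, ordered
    by decreasing singular value.
    """
    X = V.to_numpy(dtype=float) if isinstance(V, pd.DataFrame) else np.asarray(V, dtype=float)
    if np.isnan(X).any():
        raise ValueError("input contains missing values")
    if not 1 <= n_components <= min(X.shape):
        raise ValueError(f"n_components must be in [1, {min(X.shape)}]")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return (s[:n_components, None] * Vt[:n_components]).T


class PCAKMeans:
    """PCA score extraction followed by k-means clustering.

    Parameters
    ----------
    V : genes x samples matrix (DataFrame or ndarray), no missing values.
    k : number of clusters; also the number of PC score columns retained
        unless ``n_components`` overrides it.
    """

    def __init__(self, V, k: int, n_components: int | None = None):
        self.sample_ids = list(V.columns) if isinstance(V, pd.DataFrame) else None
        self.V = V.to_numpy(dtype=float) if isinstance(V, pd.DataFrame) else np.asarray(V, dtype=float)
        if not 1 <= k <= self.V.shape[1]:
            raise ValueError("k must be in [1, n_samples]")
        self.k = int(k)
        self.n_components = int(n_components) if n_components else self.k

    def fit(self, *, seed: int | None = None, n_restarts: int = 20) -> "PCAKMeansResults":
        """Cluster the score matrix; best of ``n_restarts`` by WCSS."""
        scores = pca_scores(self.V, min(self.n_components, *self.V.shape))
        km = KMeans(n_clusters=self.k, n_init=n_restarts, algorithm="lloyd",
                    random_state=None if seed is None else int(seed) % (2**32))
        labels = km.fit_predict(scores) + 1
        return PCAKMeansResults(model=self, scores=scores, labels=labels,
                                wcss=float(km.inertia_), centers=km.cluster_centers_)


class PCAKMeansResults:
    """Scores, labels, centroids and the within-cluster sum of squares."""

    def __init__(self, model: PCAKMeans, scores: np.ndarray, labels: np.ndarray,
                 wcss: float, centers: np.ndarray):
        self.model = model
        self.scores = scores
        self.labels = labels
        self.wcss = wcss
        self.centers = centers
        self.k = model.k

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.model.sample_ids, columns=cols)

    def summary(self) -> str:
        sizes = {f"cluster {c}": int((self.labels == c).sum())
                 for c in range(1, self.k + 1)}
        return "\n".join([
            "PCA-K clustering",
            f"  components retained : {self.scores.shape[1]}",
            f"  k                   : {self.k}",
            f"  WCSS                : {self.wcss:.6g}",
            f"  cluster sizes       : {sizes}",
        ])


def pca_k_cluster(V, k: int, seed: int | None = None, n_restarts: int = 20) -> np.ndarray:
    """Functional wrapper returning 1-based cluster labels."""
    return PCAKMeans(V, k).fit(seed=seed, n_restarts=n_restarts).labels
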