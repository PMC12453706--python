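"""Graph views: KNN adjacency, K-means hypergraph, and the normalized Laplacian.

Two complementary views are built per entity type from the fused node
features.  The KNN graph links each node to its k nearest neighbours in
Euclidean feature space (symmetric OR-union) and is lifted to a hypergraph
with one hyperedge per closed neighbourhood, so the same hypergraph
convolution operator serves both views.  The K-means view groups nodes into
clusters and treats each cluster as one hyperedge.  Both views are reduced to
the symmetric propagation operator

    L = Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}

whose spectrum lies in [0, 1] for unit hyperedge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "HypergraphView",
    "knn_adjacency",
    "kmeans_incidence",
    "adjacency_to_incidence",
    "hypergraph_laplacian",
    "build_views",
]


@dataclass
class HypergraphView:
    """Incidence matrix H, hyperedge weights W (diagonal), and Laplacian L."""

    H: np.ndarray
    W: np.ndarray
    L: np.ndarray
    view_tag: str = ""

    n_nodes: int = field(init=False)
    n_hyperedges: int = field(init=False)

    def __post_init__(self):
        self.n_nodes, self.n_hyperedges = self.H.shape


def knn_adjacency(X: np.ndarray, k: int) -> np.ndarray:
    """Symmetric binary KNN adjacency: edge iff either endpoint is among the
    other's k Euclidean nearest neighbours.  Self-loops excluded; ties in
    distance broken toward the lower node index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    # lexsort on (index, distance): stable tie-break toward lower index
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    A = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    A[rows, order[:, :k].ravel()] = 1
    A = np.maximum(A, A.T)  # OR-union symmetrization
    return A


def kmeans_incidence(X: np.ndarray, n_clusters: int, seed: int = 0,
                     n_init: int = 10) -> HypergraphView:
    """K-means clusters as hyperedges: H[i, c] = 1 iff node i is in cluster c.

    k-means++ initialisation with ``n_init`` restarts under a fixed seed;
    empty clusters (possible when k-means converges with fewer occupied
    centroids) are dropped so every hyperedge is nonempty.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    H = np.zeros((n, n_clusters), dtype=np.int8)
    H[np.arange(n), labels] = 1
    H = H[:, H.sum(axis=0) > 0]
    W = np.eye(H.shape[1])
    return HypergraphView(H, W, hypergraph_laplacian(H, W), view_tag="kmeans")


def adjacency_to_incidence(A: np.ndarray) -> HypergraphView:
    """Lift a simple graph to a hypergraph of closed neighbourhoods.

    Hyperedge i contains node i and its neighbours, i.e. H = A + I, the
    canonical hypergraph representation of a KNN graph.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    H = (A + np.eye(A.shape[0], dtype=A.dtype)).astype(np.int8)
    W = np.eye(H.shape[1])
    return HypergraphView(H, W, hypergraph_laplacian(H, W), view_tag="knn")


def hypergraph_laplacian(H: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
    """Normalized propagation operator Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}.

    Node degrees are row sums of H W; hyperedge degrees are column sums of H.
    Zero-degree nodes use the pseudo-inverse convention (their Dv^{-1/2} entry
    is 0), so isolated nodes receive and emit no signal.
    """
    H = np.asarray(H, dtype=float)
    n, m = H.shape
    W = np.eye(m) if W is None else np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = np.diag(W)
    w = np.diag(W)
    if np.any(w < 0):
        raise ValueError("hyperedge weights must be nonnegative")
    if np.any(H.sum(axis=0) == 0):
        raise ValueError("incidence matrix has empty hyperedges")
    dv = H @ w  # node degrees
    de = H.sum(axis=0)  # hyperedge degrees
    with np.errstate(divide="ignore"):
        dv_inv_sqrt = np.where(dv > 0, dv ** -0.5, 0.0)
        de_inv = np.where(de > 0, 1.0 / de, 0.0)
    Hn = dv_inv_sqrt[:, None] * H
    L = (Hn * (w * de_inv)[None, :]) @ Hn.T
    return 0.5 * (L + L.T)


def build_views(X: np.ndarray, k_neigs: int, n_clusters: int,
                seed: int = 0) -> tuple[HypergraphView, HypergraphView]:
    """Both graph views for one entity type from its fused features.

    ``k_neigs`` and ``n_clusters`` are clipped to the valid range for small
    node counts so the same configuration serves datasets of any size.
    """
    n = np.asarray(X).shape[0]
    k = int(min(max(k_neigs, 1), n - 1))
    c = int(min(max(n_clusters, 1), n))
    knn_view = adjacency_to_incidence(knn_adjacency(X, k))
    km_view = kmeans_incidence(X, c, seed=seed)
    return knn_view, km_view
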