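"""Shared spatial/feature kNN machinery.

Deterministic k-nearest-neighbour queries (ties broken by cell id), symmetric
kNN graphs, connected components, and Leiden community detection on a kNN
graph.  Every spatial stage of the pipeline (windows, islet extraction, CN
instances) and both feature-space clustering stages route through here so the
tie-breaking and symmetrisation conventions are defined once.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

__all__ = [
    "knn_indices",
    "symmetric_knn_graph",
    "connected_component_labels",
    "leiden_cluster",
]


def knn_indices(coords: np.ndarray, k: int, order_key: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k nearest neighbours of every point, excluding itself.

    Ties at equal Euclidean distance are broken by ascending ``order_key``
    (defaults to row index), so the result is fully deterministic even on
    degenerate inputs such as grid points or duplicated coordinates.

    Parameters
    ----------
    coords : (n, d) float array
    k : number of neighbours; requires ``k < n``
    order_key : (n,) sortable array used for tie-breaking

    Returns
    -------
    (n, k) integer array of row indices, each row sorted by (distance, key).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    if order_key is None:
        order_key = np.arange(n)
    else:
        order_key = np.asarray(order_key)

    tree = cKDTree(coords)
    m = min(n, k + 2)
    rows = np.arange(n)
    while True:
        dist, idx = tree.query(coords, k=m)
        self_pos = idx == rows[:, None]
        # keep the m-1 non-self candidates per row (pad rows whose self entry
        # was crowded out by >= m coincident points; the tie check below then
        # forces a larger m)
        has_self = self_pos.any(axis=1)
        drop = np.where(has_self, self_pos.argmax(axis=1), m - 1)
        keep = np.ones((n, m), dtype=bool)
        keep[rows, drop] = False
        cand_idx = idx[keep].reshape(n, m - 1)
        cand_dist = dist[keep].reshape(n, m - 1)

        # lexicographic (distance, key) via key-sort then stable distance-sort
        by_key = np.argsort(order_key[cand_idx], axis=1, kind="stable")
        cand_idx = np.take_along_axis(cand_idx, by_key, axis=1)
        cand_dist = np.take_along_axis(cand_dist, by_key, axis=1)
        by_dist = np.argsort(cand_dist, axis=1, kind="stable")
        cand_idx = np.take_along_axis(cand_idx, by_dist, axis=1)
        cand_dist = np.take_along_axis(cand_dist, by_dist, axis=1)

        if m == n:
            return cand_idx[:, :k]
        # unambiguous iff the k-th kept distance is strictly below the query
        # horizon; otherwise unseen equidistant points could beat kept ones
        if np.all(cand_dist[:, k - 1] < dist[:, -1]) and np.all(has_self):
            return cand_idx[:, :k]
        m = min(n, 2 * m)


def symmetric_knn_graph(coords: np.ndarray, k: int, order_key: np.ndarray | None = None) -> sp.csr_matrix:
    """Boolean adjacency with an edge wherever either point lists the other
    among its ``k`` nearest neighbours."""
    nbrs = knn_indices(coords, k, order_key)
    n = len(coords)
    rows = np.repeat(np.arange(n), k)
    a = sp.coo_matrix((np.ones(n * k, dtype=bool), (rows, nbrs.ravel())), shape=(n, n))
    a = a.tocsr()
    return (a + a.T).astype(bool)


def connected_component_labels(adjacency: sp.spmatrix) -> np.ndarray:
    _, labels = _cc(adjacency, directed=False)
    return labels


def leiden_cluster(
    X: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    metric: str = "euclidean",
) -> np.ndarray:
    """Leiden community detection on the symmetric kNN graph of the rows of X.

    ``metric='cosine'`` is implemented by L2-normalising rows first (cosine
    and Euclidean kNN orderings coincide on the unit sphere).  Rows with zero
    norm are left at the origin.
    """
    import igraph
    import leidenalg

    X = np.asarray(X, dtype=float)
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)
    elif metric != "euclidean":
        raise ValueError(f"unsupported metric: {metric!r}")
    adj = symmetric_knn_graph(X, n_neighbors)
    src, dst = sp.triu(adj, k=1).nonzero()
    g = igraph.Graph(n=X.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)
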