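"""Shared nearest-neighbor graph clustering (Seurat-style).

kNN graph in PCA space, edges reweighted by the Jaccard overlap of the
two endpoints' neighbor sets, weak edges pruned, then modularity
community detection (Leiden, RB-configuration objective).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def snn_graph(points: np.ndarray, n_neighbors: int = 20, prune: float = 1.0 / 15):
    """Jaccard-weighted shared-neighbor graph over rows of ``points``.

    Returns an igraph Graph with a ``weight`` edge attribute.  Each
    point's neighbor set includes itself, matching the convention that a
    cell is its own nearest neighbor.
    """
    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = points.shape[0]
    k = min(n_neighbors, n)
    nn = NearestNeighbors(n_neighbors=k).fit(points)
    _, idx = nn.kneighbors(points)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = (adj @ adj.T).toarray()
    jaccard = shared / (2 * k - shared)
    np.fill_diagonal(jaccard, 0.0)
    jaccard[jaccard < prune] = 0.0
    src, dst = np.nonzero(np.triu(jaccard))
    g = igraph.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = jaccard[src, dst].tolist()
    return g


def snn_labels(
    points: np.ndarray,
    resolution: float = 0.8,
    n_neighbors: int = 20,
    prune: float = 1.0 / 15,
    seed: int = 0,
) -> np.ndarray:
    """Cluster rows of ``points`` on the SNN graph; labels start at 1."""
    import leidenalg

    g = snn_graph(points, n_neighbors=n_neighbors, prune=prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
    )
    return np.asarray(part.membership) + 1
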