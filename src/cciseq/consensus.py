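"""Consensus matrix construction by repeated gene subsampling.

Each of ``m`` iterations samples a proportion ``p`` of a variable-gene
pool, embeds the cells (PCA then 2-D UMAP on the scaled subset),
clusters the embedding (K-means by default), and records a binary
co-membership matrix.  The average of the ``m`` co-membership matrices
is the consensus matrix: entry (i, j) is the fraction of runs in which
cells i and j landed in the same cluster, a robust cell-to-cell
similarity that drives imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .normalize import NormalizedMatrix, scale_genes, select_variable_genes

__all__ = [
    "CCIParams",
    "CoMembershipMatrix",
    "ConsensusMatrix",
    "subsample_genes",
    "embed_subset",
    "cluster_subset",
    "co_membership",
    "build_consensus",
]


@dataclass(frozen=True)
class CCIParams:
    """Tunables of the consensus-imputation pipeline.

    The defaults are the configuration selected by sensitivity analysis:
    sample ``p = 0.8`` of the top 100 variable genes, ``m = 50``
    iterations of K-means with ``k = 4`` on a 2-D UMAP embedding, and a
    neighbor cutoff ``c = 0.2`` on the consensus similarities.  ``k``
    deliberately overstates the expected number of groups so that no
    assumption about the true cluster count is baked in.
    """

    p: float = 0.8
    gene_pool: int | str = 100  # "all" uses every gene
    k: int = 4
    m: int = 50
    c: float = 0.2
    epsilon: float = 1e-6
    weighting: str = "weighted"
    cluster_method: str = "kmeans"
    seed: int = 0
    pca_components: int = 5
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    umap_n_epochs: int = 200
    kmeans_restarts: int = 10
    snn_resolution: float = 0.8
    snn_neighbors: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not (0 <= self.c <= 1):
            raise ValueError(f"c must be in [0, 1], got {self.c}")
        if not (self.epsilon > 0 and math.isfinite(self.epsilon)):
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.weighting not in ("weighted", "unweighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.cluster_method not in ("kmeans", "snn"):
            raise ValueError(f"unknown cluster_method {self.cluster_method!r}")
        if self.gene_pool != "all" and (
            not isinstance(self.gene_pool, (int, np.integer)) or self.gene_pool < 2
        ):
            raise ValueError(f"gene_pool must be an integer >= 2 or 'all', got {self.gene_pool!r}")


@dataclass
class CoMembershipMatrix:
    """Binary same-cluster indicator for one clustering run."""

    entries: np.ndarray


@dataclass
class ConsensusMatrix:
    """Cell-by-cell co-clustering frequency over ``m_used`` runs."""

    entries: np.ndarray
    m_used: int
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_ids:
            self.cell_ids = [f"Cell{i + 1}" for i in range(self.entries.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.entries.shape[0]


def subsample_genes(gene_ids: list[str], p: float, rng: np.random.Generator) -> list[str]:
    """Draw ``floor(p * len(gene_ids))`` distinct genes uniformly."""
    if not gene_ids:
        raise ValueError("gene list is empty")
    size = int(np.floor(p * len(gene_ids)))
    if size < 2:
        raise ValueError(
            f"subsample of {size} gene(s) from {len(gene_ids)} at p={p} is too small to embed"
        )
    chosen = rng.choice(len(gene_ids), size=size, replace=False)
    return [gene_ids[i] for i in chosen]


def embed_subset(
    scaled_values: np.ndarray,
    random_state: int = 0,
    pca_components: int = 5,
    umap_n_neighbors: int = 15,
    umap_min_dist: float = 0.1,
    umap_n_epochs: int | None = 200,
) -> np.ndarray:
    """PCA then 2-D UMAP of a scaled gene-by-cell subset.

    Returns a cells-by-2 embedding, deterministic given
    ``random_state``.
    """
    import warnings

    from sklearn.decomposition import PCA
    from umap import UMAP

    if np.allclose(scaled_values.std(axis=1), 0):
        raise ValueError("subset is constant across cells; cannot embed")
    cells = scaled_values.T  # cells x genes
    n_comp = min(pca_components, cells.shape[0] - 1, cells.shape[1] - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(cells)
    um = UMAP(
        n_components=2,
        n_neighbors=umap_n_neighbors,
        min_dist=umap_min_dist,
        n_epochs=umap_n_epochs,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        # setting random_state forces single-threaded layout; expected
        warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
        return np.asarray(um.fit_transform(pcs))


def cluster_subset(
    embedding: np.ndarray,
    k: int,
    rng: np.random.Generator,
    restarts: int = 10,
) -> np.ndarray:
    """K-means labels (1..k) on a cells-by-2 embedding.

    Cluster indices carry no meaning across runs; downstream use relies
    only on label equality.
    """
    from sklearn.cluster import KMeans

    n = embedding.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} cells")
    if k == 1:
        return np.ones(n, dtype=int)
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        init="k-means++",
        random_state=int(rng.integers(2**31)),
    )
    return km.fit_predict(embedding) + 1


def co_membership(labels: np.ndarray) -> CoMembershipMatrix:
    """Binary matrix with 1 where two cells share a label."""
    lab = np.asarray(labels)
    return CoMembershipMatrix((lab[:, None] == lab[None, :]).astype(np.float64))


def _iteration_labels(
    pool_scaled: np.ndarray,
    pool_ids: list[str],
    params: CCIParams,
    rng: np.random.Generator,
) -> np.ndarray:
    index = {g: i for i, g in enumerate(pool_ids)}
    subset = subsample_genes(pool_ids, params.p, rng)
    sub = pool_scaled[[index[g] for g in subset], :]
    embedding = embed_subset(
        sub,
        random_state=int(rng.integers(2**31)),
        pca_components=params.pca_components,
        umap_n_neighbors=params.umap_n_neighbors,
        umap_min_dist=params.umap_min_dist,
        umap_n_epochs=params.umap_n_epochs,
    )
    if params.cluster_method == "kmeans":
        return cluster_subset(embedding, params.k, rng, restarts=params.kmeans_restarts)
    from ._snn import snn_labels

    return snn_labels(
        embedding,
        resolution=params.snn_resolution,
        n_neighbors=params.snn_neighbors,
        seed=int(rng.integers(2**31)),
    )


def build_consensus(norm: NormalizedMatrix, params: CCIParams) -> ConsensusMatrix:
    """Run the full subsample-embed-cluster ensemble and average it.

    The variable-gene pool is selected once; each iteration re-samples
    genes from that pool.  Per-iteration RNG substreams are derived from
    ``(seed, iteration)``, so the result does not depend on execution
    order.
    """
    if norm.n_cells < params.k:
        raise ValueError(f"need at least k={params.k} cells, have {norm.n_cells}")
    if params.gene_pool == "all":
        pool_ids = list(norm.gene_ids)
    else:
        pool_ids = select_variable_genes(norm, min(int(params.gene_pool), norm.n_genes))
    scaled = norm if norm.is_scaled else scale_genes(norm)
    index = {g: i for i, g in enumerate(scaled.gene_ids)}
    pool_scaled = scaled.values[[index[g] for g in pool_ids], :]

    total = np.zeros((norm.n_cells, norm.n_cells))
    streams = np.random.SeedSequence(params.seed).spawn(params.m)
    for it, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        try:
            labels = _iteration_labels(pool_scaled, pool_ids, params, rng)
        except Exception as exc:  # noqa: BLE001 - annotate the failing iteration
            raise RuntimeError(f"consensus iteration {it} failed: {exc}") from exc
        total += co_membership(labels).entries
    total /= params.m
    return ConsensusMatrix(total, m_used=params.m, cell_ids=list(norm.cell_ids))
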