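"""Downstream-analysis evaluation: clustering, DE calling, recovery.

Implements the metrics used to judge imputation quality:

* SNN clustering of a (normalized or imputed) matrix and the adjusted
  Rand index against true group labels;
* compactness, the between-group share of total variance of the 2-D
  embedded cells under a clustering, ``B / (B + W)``;
* Wilcoxon rank-sum DE calling between two identified clusters with a
  multiplicity-adjusted p-value and log fold-change threshold, compared
  with the true DE gene set through Jaccard index, sensitivity and
  specificity;
* per-gene Spearman correlation between imputed and dropout-free data,
  averaged over true DE genes;
* a benchmark harness that simulates, corrupts, imputes and scores
  whole grids of settings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._snn import snn_labels
from .consensus import CCIParams
from .normalize import NormalizedMatrix, log_normalize
from .sim import SimParams, SimulatedDataset, apply_dropout, simulate_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "DECallResult",
    "MetricsReport",
    "snn_cluster",
    "adjusted_rand_index",
    "compactness",
    "wilcoxon_de",
    "set_metrics",
    "gene_recovery_correlation",
    "run_benchmark",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    embedding: np.ndarray | None = None  # cells x 2, for plots and compactness


@dataclass
class DECallResult:
    table: pd.DataFrame  # per gene: statistic, p, adj_p, lfc
    declared: set[str] = field(default_factory=set)
    alpha: float = 0.05
    lfc_min: float = 0.2


@dataclass
class MetricsReport:
    """One row of a benchmark summary."""

    ari: float = np.nan
    compactness: float = np.nan
    jaccard: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    mean_spearman: float = np.nan


def _values_and_ids(matrix) -> tuple[np.ndarray, list[str]]:
    from .impute import ImputedMatrix

    if isinstance(matrix, (NormalizedMatrix, ImputedMatrix)):
        return matrix.values, list(matrix.gene_ids)
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"Gene{i + 1}" for i in range(arr.shape[0])]


def snn_cluster(
    matrix,
    resolution: float = 0.2,
    n_neighbors: int = 20,
    n_pcs: int = 10,
    prune: float = 1.0 / 15,
    seed: int = 0,
    with_embedding: bool = True,
) -> ClusteringResult:
    """Shared nearest-neighbor clustering of a gene-by-cell matrix.

    Genes are scaled, cells are embedded with PCA, a kNN graph is
    Jaccard-reweighted by shared neighbors and clustered by modularity.
    A 2-D UMAP of the same PCA space is returned for visualization and
    compactness unless ``with_embedding`` is disabled.
    """
    from sklearn.decomposition import PCA

    values, _ = _values_and_ids(matrix)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cells to cluster")
    sd = values.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("matrix is constant; nothing to cluster")
    scaled = (values - values.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    cells = scaled.T
    n_comp = min(n_pcs, cells.shape[0] - 1, cells.shape[1] - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(cells)
    labels = snn_labels(
        pcs, resolution=resolution, n_neighbors=n_neighbors, prune=prune, seed=seed
    )
    embedding = None
    if with_embedding:
        from umap import UMAP

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
            embedding = np.asarray(
                UMAP(n_components=2, random_state=seed).fit_transform(pcs)
            )
    return ClusteringResult(labels=labels, embedding=embedding)


def adjusted_rand_index(a, b) -> float:
    """Permutation-model adjusted Rand index between two labelings."""
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def compactness(points: np.ndarray, labels) -> float:
    """Between-group share of total variance, ``B / (B + W)``.

    ``B`` sums ``n_k * ||mean_k - mean||^2`` over clusters and ``W``
    sums squared distances of points to their cluster mean; the two add
    up to the total sum of squares about the grand mean.  Returns 0
    (with a warning) for a single cluster, where separation is
    undefined.
    """
    pts = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        warnings.warn("compactness of a single cluster is 0 by convention", stacklevel=2)
        return 0.0
    grand = pts.mean(axis=0)
    b = 0.0
    w = 0.0
    for u in uniq:
        sel = pts[lab == u]
        center = sel.mean(axis=0)
        b += len(sel) * float(np.sum((center - grand) ** 2))
        w += float(np.sum((sel - center) ** 2))
    return b / (b + w)


def _log_fold_change(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    # Seurat-style: base-2 log of de-logged means with pseudocount 1
    mean_a = np.expm1(values_a).mean(axis=1)
    mean_b = np.expm1(values_b).mean(axis=1)
    return np.log2((mean_a + 1.0) / (mean_b + 1.0))


def wilcoxon_de(
    matrix,
    labels,
    alpha: float = 0.05,
    lfc_min: float = 0.2,
    adjust: str = "bonferroni",
) -> DECallResult:
    """Wilcoxon rank-sum DE calling between two clusters.

    If more than two clusters are supplied, the two largest are
    contrasted (and this is logged).  A gene is declared DE when its
    adjusted p-value is below ``alpha`` and the absolute log
    fold-change of the average expression reaches ``lfc_min``.
    """
    from scipy.stats import mannwhitneyu
    from statsmodels.stats.multitest import multipletests

    values, gene_ids = _values_and_ids(matrix)
    lab = np.asarray(labels)
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters for DE analysis")
    if len(uniq) > 2:
        keep = uniq[np.argsort(-counts)][:2]
        logger.info("wilcoxon_de: %d clusters, contrasting the largest two %s", len(uniq), keep)
    else:
        keep = uniq
    sel_a = lab == keep[0]
    sel_b = lab == keep[1]
    if sel_a.sum() < 3 or sel_b.sum() < 3:
        raise ValueError("each contrasted cluster needs at least 3 cells")
    a, b = values[:, sel_a], values[:, sel_b]

    constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
    with np.errstate(all="ignore"):
        stat, p = mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
    p = np.where(constant, 1.0, p)
    adj = multipletests(p, method=adjust)[1]
    lfc = _log_fold_change(a, b)
    table = pd.DataFrame(
        {"statistic": stat, "p": p, "adj_p": adj, "lfc": lfc}, index=gene_ids
    )
    declared = set(table.index[(adj < alpha) & (np.abs(lfc) >= lfc_min)])
    return DECallResult(table=table, declared=declared, alpha=alpha, lfc_min=lfc_min)


def set_metrics(declared: set, truth: set, universe: set) -> tuple[float, float | None, float]:
    """Jaccard, sensitivity and specificity of a declared DE gene set.

    Sensitivity is undefined (None) when the truth set is empty.
    """
    declared, truth, universe = set(declared), set(truth), set(universe)
    if not declared <= universe or not truth <= universe:
        raise ValueError("declared and truth must be subsets of the universe")
    union = declared | truth
    inter = declared & truth
    jaccard = len(inter) / len(union) if union else 1.0
    sensitivity = len(inter) / len(truth) if truth else None
    neg = universe - truth
    specificity = len((universe - declared) & neg) / len(neg) if neg else 1.0
    return jaccard, sensitivity, specificity


def gene_recovery_correlation(imputed, truth, de_genes) -> float:
    """Mean per-gene Spearman correlation across cells over ``de_genes``.

    Genes whose values are constant in either matrix have an undefined
    correlation and are excluded (with a logged count); if every gene is
    excluded an error is raised.
    """
    from scipy.stats import rankdata

    values_i, ids_i = _values_and_ids(imputed)
    values_t, ids_t = _values_and_ids(truth)
    if values_i.shape != values_t.shape:
        raise ValueError(
            f"matrix shapes differ: {values_i.shape} vs {values_t.shape}"
        )
    de_genes = list(de_genes)
    if not de_genes:
        raise ValueError("de_genes is empty")
    if all(isinstance(g, (int, np.integer)) for g in de_genes):
        rows = np.asarray(de_genes, dtype=int)
    else:
        index = {g: i for i, g in enumerate(ids_i)}
        rows = np.asarray([index[g] for g in de_genes])
    xi, xt = values_i[rows], values_t[rows]
    ri = rankdata(xi, axis=1)
    rt = rankdata(xt, axis=1)
    ri = ri - ri.mean(axis=1, keepdims=True)
    rt = rt - rt.mean(axis=1, keepdims=True)
    denom = np.sqrt((ri**2).sum(axis=1) * (rt**2).sum(axis=1))
    ok = denom > 0
    if not ok.any():
        raise ValueError("all per-gene correlations are undefined (constant vectors)")
    if (~ok).sum():
        logger.info("gene_recovery_correlation: %d constant gene(s) excluded", int((~ok).sum()))
    rho = (ri[ok] * rt[ok]).sum(axis=1) / denom[ok]
    return float(rho.mean())


def _evaluate_matrix(
    matrix,
    dataset: SimulatedDataset,
    truth_norm: NormalizedMatrix,
    seed: int,
    snn_kwargs: dict,
    alpha: float,
    lfc_min: float,
    with_de: bool = True,
) -> MetricsReport:
    clustering = snn_cluster(matrix, seed=seed, **snn_kwargs)
    report = MetricsReport()
    report.ari = adjusted_rand_index(dataset.group_labels, clustering.labels)
    if clustering.embedding is not None:
        report.compactness = compactness(clustering.embedding, clustering.labels)
    truth_genes = dataset.true_de_genes
    universe = set(dataset.gene_ids)
    if with_de:
        try:
            de = wilcoxon_de(matrix, clustering.labels, alpha=alpha, lfc_min=lfc_min)
            declared = de.declared
        except ValueError as exc:
            logger.info("DE calling skipped: %s", exc)
            declared = set()
        jac, sens, spec = set_metrics(declared, truth_genes, universe)
        report.jaccard = jac
        report.sensitivity = np.nan if sens is None else sens
        report.specificity = spec
    if truth_genes:
        report.mean_spearman = gene_recovery_correlation(
            matrix, truth_norm, sorted(truth_genes)
        )
    return report


def run_benchmark(
    grid: list[SimParams],
    params: CCIParams | None = None,
    reps: int = 1,
    methods: tuple[str, ...] = ("without_dropout", "with_dropout", "cci"),
    seed: int = 0,
    snn_kwargs: dict | None = None,
    alpha: float = 0.05,
    lfc_min: float = 0.2,
    with_embedding: bool = True,
    with_de: bool = True,
    external: dict | None = None,
) -> pd.DataFrame:
    """Simulate, corrupt, impute and score every grid setting.

    Returns one row per (setting, rep, method) with the metric columns
    of :class:`MetricsReport`.  Use :func:`summarize_benchmark` for the
    mean (sd) summary layout.  Per-rep failures are logged and excluded.

    ``external`` maps a method name to a callable
    ``f(dataset, corrupted_norm) -> gene-by-cell matrix`` so that
    matrices imputed by other tools can be scored alongside; the
    callable receives the simulated truth bundle and the corrupted
    log-normalized matrix it should impute.
    """
    from .impute import cci_run

    params = params or CCIParams()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    snn_kwargs = dict(snn_kwargs or {})
    snn_kwargs.setdefault("with_embedding", with_embedding)
    rows = []
    for si, base in enumerate(grid):
        for rep in range(reps):
            run_seed = seed + 1009 * si + rep
            sim = simulate_counts(
                SimParams(**{**base.__dict__, "seed": run_seed})
            )
            sim = apply_dropout(sim)
            truth_norm = log_normalize(sim.counts)
            dropped_norm = log_normalize(sim.counts_dropout)
            matrices = {}
            if "without_dropout" in methods:
                matrices["without_dropout"] = truth_norm
            if "with_dropout" in methods:
                matrices["with_dropout"] = dropped_norm
            if "cci" in methods:
                run_params = CCIParams(**{**params.__dict__, "seed": run_seed})
                matrices["cci"] = cci_run(dropped_norm, run_params).imputed
            for name, fn in (external or {}).items():
                matrices[name] = fn(sim, dropped_norm)
            for method, matrix in matrices.items():
                try:
                    report = _evaluate_matrix(
                        matrix, sim, truth_norm, run_seed, snn_kwargs, alpha, lfc_min,
                        with_de=with_de,
                    )
                except Exception as exc:  # noqa: BLE001 - keep the benchmark going
                    logger.warning(
                        "setting %d rep %d method %s failed: %s", si, rep, method, exc
                    )
                    continue
                rows.append(
                    {
                        "setting": si,
                        "de_fac_loc": base.de_fac_loc,
                        "dropout_mid": base.dropout_mid,
                        "rep": rep,
                        "method": method,
                        **report.__dict__,
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-means (and mean-of-sds) summary across settings per method."""
    metrics = ["ari", "compactness", "jaccard", "sensitivity", "specificity", "mean_spearman"]
    per_setting = results.groupby(["method", "setting"])[metrics].agg(["mean", "std"])
    summary = per_setting.groupby("method").mean()
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return summary
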