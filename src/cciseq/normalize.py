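"""Log normalization, per-gene scaling and variable-gene selection.

``log_normalize`` divides each cell's counts by the cell total, rescales
to a fixed factor (default 10,000) and applies log1p, so zeros map to
exactly zero and library-size differences are removed.  ``scale_genes``
centers and standardizes each gene, and is used only for embeddings —
imputation always consumes the unscaled log-normalized matrix, which
lives on the expression scale that neighbor averaging expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "NormalizedMatrix",
    "log_normalize",
    "scale_genes",
    "select_variable_genes",
]


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # gene x cell, log scale
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    scale_factor: float = 10_000.0
    is_scaled: bool = False

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = [f"Gene{i + 1}" for i in range(self.values.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"Cell{i + 1}" for i in range(self.values.shape[1])]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _as_dense_counts(counts) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(counts, ExpressionMatrix):
        return counts.dense(), list(counts.gene_ids), list(counts.cell_ids)
    arr = np.asarray(counts)
    return (
        arr,
        [f"Gene{i + 1}" for i in range(arr.shape[0])],
        [f"Cell{i + 1}" for i in range(arr.shape[1])],
    )


def log_normalize(counts, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize a gene-by-cell count matrix, then log1p.

    ``value[g, c] = log1p(counts[g, c] * scale_factor / total_c)``.
    Cells with zero total are rejected by name: they carry no
    information and should be filtered upstream.
    """
    values, gene_ids, cell_ids = _as_dense_counts(counts)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    totals = values.sum(axis=0)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        names = ", ".join(cell_ids[i] for i in empty[:5])
        raise ValueError(f"cells with zero total counts: {names}")
    norm = np.log1p(values * (scale_factor / totals)[None, :])
    return NormalizedMatrix(norm, gene_ids, cell_ids, scale_factor=scale_factor)


def scale_genes(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Center each gene and scale to unit standard deviation.

    Constant genes become all-zero rows instead of dividing by zero.
    """
    if norm.is_scaled:
        raise ValueError("matrix is already scaled")
    mu = norm.values.mean(axis=1, keepdims=True)
    sd = norm.values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    scaled = (norm.values - mu) / sd
    return NormalizedMatrix(
        scaled,
        list(norm.gene_ids),
        list(norm.cell_ids),
        scale_factor=norm.scale_factor,
        is_scaled=True,
    )


def variable_gene_statistic(norm: NormalizedMatrix) -> np.ndarray:
    """Variance-stabilized dispersion statistic used to rank genes.

    Computed the way the standard variable-feature selection of
    single-cell toolkits does (vst): per-gene mean and variance are
    taken on the de-logged, library-normalized scale, a lowess trend of
    log10 variance against log10 mean predicts the expected standard
    deviation for each gene, values are standardized against that
    expectation and clipped at sqrt(n_cells), and the statistic is the
    variance of the clipped standardized values.  Genes whose observed
    variance exceeds what their expression level predicts — dropout
    bimodality and genuine group differences, not sheer depth — rank
    highest.  Constant genes score ``-inf`` so they sort last.
    """
    if norm.is_scaled:
        raise ValueError("variable genes are selected before per-gene scaling")
    x = np.expm1(norm.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    stat = np.full(x.shape[0], -np.inf)
    ok = (var > 0) & (mean > 0)
    if ok.sum() < 2:
        return stat
    from statsmodels.nonparametric.smoothers_lowess import lowess

    trend = lowess(np.log10(var[ok]), np.log10(mean[ok]), frac=0.3, return_sorted=False)
    sd_expected = np.sqrt(10.0**trend)
    clip = np.sqrt(x.shape[1])
    z = (x[ok] - mean[ok][:, None]) / sd_expected[:, None]
    np.clip(z, -clip, clip, out=z)
    stat[ok] = z.var(axis=1, ddof=1)
    return stat


def select_variable_genes(norm: NormalizedMatrix, n: int) -> list[str]:
    """Top ``n`` most variable genes, most variable first.

    Ties are broken by higher mean expression, then lexicographic gene
    id, so the ranking is deterministic and invariant to row order.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > norm.n_genes:
        raise ValueError(f"n={n} exceeds the {norm.n_genes} available genes")
    stat = variable_gene_statistic(norm)
    mean = norm.values.mean(axis=1)
    order = sorted(
        range(norm.n_genes),
        key=lambda i: (-stat[i], -mean[i], norm.gene_ids[i]),
    )
    return [norm.gene_ids[i] for i in order[:n]]
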