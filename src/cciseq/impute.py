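"""Neighbor weights and zero-count imputation from a consensus matrix.

A cutoff ``c`` on the consensus similarities defines each cell's
neighbors; zero entries are then replaced by the (weighted or plain)
average of the same gene over those neighbors, with an epsilon in the
denominator so that a cell with no qualifying neighbor keeps its zero —
the biological-zero-preserving behavior of consensus imputation.
Nonzero entries are never touched.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .consensus import CCIParams, ConsensusMatrix, build_consensus
from .matrix import ExpressionMatrix
from .normalize import NormalizedMatrix, log_normalize

__all__ = [
    "NeighborWeights",
    "ImputedMatrix",
    "neighbor_weights",
    "impute_weighted",
    "impute_unweighted",
    "cci_run",
    "CCIResult",
]


@dataclass
class NeighborWeights:
    """Cutoff-thresholded consensus similarities; self-weight zeroed."""

    weights: np.ndarray
    cutoff: float


@dataclass
class ImputedMatrix:
    values: np.ndarray  # gene x cell, log-normalized scale
    imputed_mask: np.ndarray  # True exactly where the input was zero
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    @property
    def n_imputed(self) -> int:
        return int(self.imputed_mask.sum())


@dataclass
class CCIResult:
    """Output bundle of :func:`cci_run`."""

    imputed: ImputedMatrix
    consensus: ConsensusMatrix
    params: CCIParams
    normalized: NormalizedMatrix
    timings: dict = field(default_factory=dict)


def neighbor_weights(consensus: ConsensusMatrix, c: float) -> NeighborWeights:
    """Keep consensus entries >= ``c``; zero the rest and the diagonal.

    The cell's own similarity is always 1, but its value at a zero
    entry is 0, so including it would only deflate the estimates; the
    self-weight is therefore excluded.
    """
    if not (0 <= c <= 1):
        raise ValueError(f"cutoff must be in [0, 1], got {c}")
    w = np.where(consensus.entries >= c, consensus.entries, 0.0)
    np.fill_diagonal(w, 0.0)
    return NeighborWeights(weights=w, cutoff=float(c))


def _impute(norm: NormalizedMatrix, weights: np.ndarray, epsilon: float) -> ImputedMatrix:
    x = norm.values
    if weights.shape != (x.shape[1], x.shape[1]):
        raise ValueError(
            f"weights are {weights.shape} but the matrix has {x.shape[1]} cells"
        )
    zero = x == 0
    # x @ W.T: for target cell i, sum_k w_ik * x[g, k]
    estimates = (x @ weights.T) / (weights.sum(axis=1)[None, :] + epsilon)
    values = np.where(zero, estimates, x)
    return ImputedMatrix(
        values=values,
        imputed_mask=zero,
        gene_ids=list(norm.gene_ids),
        cell_ids=list(norm.cell_ids),
    )


def impute_weighted(
    norm: NormalizedMatrix, weights: NeighborWeights, epsilon: float = 1e-6
) -> ImputedMatrix:
    """Weighted neighbor average at every zero entry.

    ``x_hat[g, i] = sum_k w_ik x[g, k] / (sum_k w_ik + epsilon)`` over
    neighbors ``k != i``.
    """
    return _impute(norm, weights.weights, epsilon)


def impute_unweighted(
    norm: NormalizedMatrix, weights: NeighborWeights, epsilon: float = 1e-6
) -> ImputedMatrix:
    """Plain average over qualifying neighbors at every zero entry."""
    return _impute(norm, (weights.weights > 0).astype(float), epsilon)


def cci_run(
    data,
    params: CCIParams | None = None,
    normalized: bool = False,
) -> CCIResult:
    """Full pipeline: normalize, build consensus, impute zeros.

    ``data`` may be raw counts (gene-by-cell array or
    :class:`ExpressionMatrix`), which are log-normalized internally, or
    an already-normalized :class:`NormalizedMatrix` (or an array with
    ``normalized=True``).  Values are imputed on the log-normalized
    scale and stay there; downstream DE and correlation analyses
    consume normalized data.
    """
    params = params or CCIParams()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if isinstance(data, NormalizedMatrix):
        norm = data
    elif normalized:
        arr = data.dense() if isinstance(data, ExpressionMatrix) else np.asarray(data, dtype=float)
        ids = (
            (list(data.gene_ids), list(data.cell_ids))
            if isinstance(data, ExpressionMatrix)
            else ([], [])
        )
        norm = NormalizedMatrix(arr, *ids)
    else:
        norm = log_normalize(data)
    if norm.is_scaled:
        raise ValueError("imputation consumes the unscaled log-normalized matrix")
    timings["normalize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    consensus = build_consensus(norm, params)
    timings["consensus"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    weights = neighbor_weights(consensus, params.c)
    if params.weighting == "weighted":
        imputed = impute_weighted(norm, weights, params.epsilon)
    else:
        imputed = impute_unweighted(norm, weights, params.epsilon)
    timings["impute"] = time.perf_counter() - t0

    return CCIResult(
        imputed=imputed,
        consensus=consensus,
        params=params,
        normalized=norm,
        timings=timings,
    )
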