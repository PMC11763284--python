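"""Core in-memory containers shared across the package.

All matrices are stored gene-by-cell: rows are genes, columns are cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


@dataclass
class ExpressionMatrix:
    """A gene-by-cell expression matrix with identifiers.

    The same container is used for raw counts, normalized values and
    imputed values; ``role`` records which stage produced it.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    role: str = "counts"

    def __post_init__(self) -> None:
        n_genes, n_cells = self.values.shape
        if not self.gene_ids:
            self.gene_ids = _default_ids("Gene", n_genes)
        if not self.cell_ids:
            self.cell_ids = _default_ids("Cell", n_cells)
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)
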