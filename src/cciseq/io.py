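"""Reading and writing expression matrices and run artifacts.

Matrices travel as Matrix Market triplets (matrix.mtx with genes.tsv /
barcodes.tsv alongside, 10x-style) or as dense CSV/TSV with gene rows
and cell columns.  Everything is stored gene-by-cell; readers accept
the transposed orientation through a flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import ExpressionMatrix

__all__ = ["read_matrix", "write_matrix"]

_DELIMS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if path.is_dir() or suffix == "mtx":
        return "mtx"
    if suffix in _DELIMS:
        return suffix
    raise ValueError(f"cannot infer format of {path}; pass format explicitly")


def read_matrix(
    path,
    format: str | None = None,
    genes_as_rows: bool = True,
) -> ExpressionMatrix:
    """Load an expression matrix.

    For ``mtx``, ``path`` may be the .mtx file or a directory holding
    ``matrix.mtx``; ``genes.tsv`` and ``barcodes.tsv`` next to it are
    used for identifiers when present.  Sparse input stays sparse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        values = sp.csr_matrix(scipy.io.mmread(mtx_path))
        folder = mtx_path.parent
        gene_ids: list[str] = []
        cell_ids: list[str] = []
        genes_file = folder / "genes.tsv"
        barcodes_file = folder / "barcodes.tsv"
        if genes_file.exists():
            gene_ids = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        if barcodes_file.exists():
            cell_ids = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
        if not genes_as_rows:
            values = values.T
            gene_ids, cell_ids = cell_ids, gene_ids
        n_genes, n_cells = values.shape
        if gene_ids and len(gene_ids) != n_genes:
            raise ValueError(
                f"genes.tsv lists {len(gene_ids)} genes but the matrix has {n_genes} rows"
            )
        if cell_ids and len(cell_ids) != n_cells:
            raise ValueError(
                f"barcodes.tsv lists {len(cell_ids)} cells but the matrix has {n_cells} columns"
            )
        return ExpressionMatrix(values, gene_ids, cell_ids)
    frame = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0)
    if not genes_as_rows:
        frame = frame.T
    return ExpressionMatrix(
        frame.to_numpy(dtype=float),
        frame.index.astype(str).tolist(),
        frame.columns.astype(str).tolist(),
    )


def write_matrix(matrix: ExpressionMatrix, path, format: str | None = None) -> Path:
    """Write a matrix; the mirror of :func:`read_matrix`.

    ``mtx`` writes a triplet directory (matrix.mtx, genes.tsv,
    barcodes.tsv).  Output ordering is deterministic: genes then cells,
    in stored order.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        folder = path if path.suffix.lower() != ".mtx" else path.parent
        folder.mkdir(parents=True, exist_ok=True)
        mtx_path = folder / "matrix.mtx" if path.suffix.lower() != ".mtx" else path
        values = matrix.values
        sparse = sp.coo_matrix(values) if not sp.issparse(values) else values.tocoo()
        scipy.io.mmwrite(str(mtx_path), sparse)
        pd.Series(matrix.gene_ids).to_csv(
            mtx_path.parent / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(matrix.cell_ids).to_csv(
            mtx_path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
        return mtx_path
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
    frame.to_csv(path, sep=_DELIMS[fmt])
    return path
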