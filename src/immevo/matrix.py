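"""Gene x cell expression matrix container and plain-text I/O.

Matrices are pandas DataFrames with gene ids as the index and cell ids as
columns.  The ``unit`` tag distinguishes linear TPM from the log scale
E = log2(TPM + 1) and guards against double transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_mtx",
    "read_matrix_mtx",
]

VALID_UNITS = ("TPM", "counts", "E")


@dataclass
class ExpressionMatrix:
    """A gene x cell matrix with a unit tag.

    ``values``: DataFrame, genes as rows, cells as columns.
    ``unit``: "TPM" (linear), "counts" (estimated counts), or "E" (log2(TPM+1)).
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.unit in ("TPM", "counts") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values are not valid {self.unit}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(cells)].copy(), self.unit)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.unit)


def read_matrix_tsv(path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a genes-x-cells TSV (header row of cell ids, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, unit)


def write_matrix_tsv(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def write_matrix_mtx(m: ExpressionMatrix, prefix) -> None:
    """Write MatrixMarket triplet plus gene/cell id sidecar files.

    ``prefix`` is extended to ``<prefix>.mtx``, ``<prefix>.genes.txt`` and
    ``<prefix>.cells.txt``.
    """
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(m.values.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(m.genes) + "\n")
    prefix.with_suffix(".cells.txt").write_text("\n".join(m.cells) + "\n")


def read_matrix_mtx(prefix, unit: str = "TPM") -> ExpressionMatrix:
    from scipy import io as spio

    prefix = Path(prefix)
    mat = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    cells = prefix.with_suffix(".cells.txt").read_text().splitlines()
    return ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=cells), unit)
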