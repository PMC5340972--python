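"""Expression quality control: log transform, cell filters, pseudobulk agreement.

Expression is quantified as E = log2(TPM + 1).  Cells with fewer than 500
detected genes (TPM > 0) or fewer than 10,000 reads mapped to transcripts are
excluded; the boundaries are strict ("fewer than"), so exactly 500 genes or
10,000 reads pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["QCReport", "log_transform", "qc_filter", "pseudobulk_correlation"]


@dataclass
class QCReport:
    """Per-cell QC outcome plus aggregate counts."""

    per_cell: pd.DataFrame  # detected_genes, mapped_reads, passed, reasons
    n_input: int
    n_removed: int
    n_retained: int
    mean_detected_genes: float
    mean_detected_genes_retained: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_removed": self.n_removed,
                "n_retained": self.n_retained,
                "mean_detected_genes": self.mean_detected_genes,
                "mean_detected_genes_retained": self.mean_detected_genes_retained,
            },
            indent=2,
        )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """E = log2(TPM + 1); rejects already-transformed input via the unit tag."""
    if m.unit != "TPM":
        raise ValueError(f"log_transform expects TPM input, got unit {m.unit!r}")
    return ExpressionMatrix(np.log2(m.values + 1.0), "E")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """TPM = 2**E - 1, the exact inverse of :func:`log_transform`."""
    if m.unit != "E":
        raise ValueError(f"inverse_log_transform expects E input, got unit {m.unit!r}")
    return ExpressionMatrix(np.maximum(np.power(2.0, m.values) - 1.0, 0.0), "TPM")


def qc_filter(
    m: ExpressionMatrix,
    reads_per_cell: pd.Series,
    min_genes: int = 500,
    min_reads: int = 10_000,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove cells with < ``min_genes`` detected genes or < ``min_reads`` reads.

    A gene is "detected" when its TPM is strictly positive.  Surviving cells'
    values are untouched, so the filter is idempotent.
    """
    if m.unit != "TPM":
        raise ValueError("qc_filter expects a TPM matrix")
    reads_per_cell = pd.Series(reads_per_cell)
    if set(reads_per_cell.index) != set(m.cells):
        raise ValueError("reads_per_cell index does not match the matrix cell ids")
    reads = reads_per_cell.loc[m.cells]
    detected = (m.values > 0).sum(axis=0)
    reasons = []
    passed = []
    for cell in m.cells:
        r = []
        if detected[cell] < min_genes:
            r.append(f"detected genes {detected[cell]} < {min_genes}")
        if reads[cell] < min_reads:
            r.append(f"mapped reads {reads[cell]} < {min_reads}")
        reasons.append("; ".join(r))
        passed.append(not r)
    per_cell = pd.DataFrame(
        {
            "detected_genes": detected.astype(int),
            "mapped_reads": reads,
            "passed": passed,
            "reasons": reasons,
        },
        index=m.cells,
    )
    keep = per_cell.index[per_cell["passed"]]
    filtered = m.subset_cells(keep)
    report = QCReport(
        per_cell=per_cell,
        n_input=m.n_cells,
        n_removed=int(m.n_cells - len(keep)),
        n_retained=int(len(keep)),
        mean_detected_genes=float(detected.mean()),
        mean_detected_genes_retained=float(detected[keep].mean()) if len(keep) else float("nan"),
    )
    return filtered, report


def pseudobulk_correlation(m: ExpressionMatrix, bulk: pd.Series) -> float:
    """Pearson correlation of the cellwise-mean E profile with a bulk profile.

    Computed on the gene intersection; fewer than 3 shared genes, or a
    zero-variance profile, is an error rather than a NaN.
    """
    if m.unit != "E":
        raise ValueError("pseudobulk_correlation expects an E-unit matrix")
    shared = m.genes.intersection(bulk.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    x = m.values.loc[shared].mean(axis=1).to_numpy(dtype=float)
    y = bulk.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance profile; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
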