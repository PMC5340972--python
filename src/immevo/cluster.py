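"""Correlation dissimilarity, classical MDS, EB batch adjustment, Ward clustering.

Cell-to-cell dissimilarity is 1 - Pearson correlation over full transcriptional
profiles.  Classical MDS (principal coordinates analysis) embeds the
dissimilarity matrix by Torgerson double-centering and eigendecomposition.
Batch effects are removed with a parametric empirical-Bayes location-scale
model (per-gene batch means and variances shrunk toward common priors).
Hierarchical clustering uses Ward's criterion (Ward.D2, i.e. on Euclidean
distances) on the first four principal coordinates, and the number of clusters
is chosen by maximizing the mean silhouette coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from sklearn.metrics import silhouette_score

from .matrix import ExpressionMatrix

__all__ = [
    "DissimilarityMatrix",
    "Embedding",
    "ClusterResult",
    "pcc_dissimilarity",
    "classical_mds",
    "eb_batch_adjust",
    "ward_cluster",
]


@dataclass
class DissimilarityMatrix:
    """Square symmetric 1 - PCC matrix with zero diagonal, entries in [0, 2]."""

    values: np.ndarray
    cell_ids: list

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("dissimilarity matrix must be symmetric")


@dataclass
class Embedding:
    """Cell x k principal-coordinate matrix with descending eigenvalues."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    cell_ids: list


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1..k, relabelled so cluster 1 is the largest
    k: int
    silhouette_by_k: dict = field(default_factory=dict)
    linkage: np.ndarray | None = None
    cell_ids: list = field(default_factory=list)


def pcc_dissimilarity(m: ExpressionMatrix) -> DissimilarityMatrix:
    """D[a, b] = 1 - PCC(cell a, cell b) over all genes."""
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    X = m.values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(f"constant expression profile for cell {m.cells[flat[0]]!r}")
    C = np.corrcoef(X.T)
    D = 1.0 - C
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(values=np.clip(D, 0.0, 2.0), cell_ids=list(m.cells))


def classical_mds(d: DissimilarityMatrix, k: int) -> Embedding:
    """Principal coordinates analysis by Torgerson double-centering.

    B = -1/2 J D^2 J; coordinates are the top-k eigenvectors scaled by the
    square root of their (nonnegative) eigenvalues; axes with negative
    eigenvalues are zeroed.
    """
    n = d.values.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n (= {n})")
    D2 = d.values**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    scale = np.sqrt(np.clip(evals[:k], 0.0, None))
    coords = evecs[:, :k] * scale[None, :]
    coords = coords - coords.mean(axis=0, keepdims=True)
    return Embedding(coords=coords, eigenvalues=evals, cell_ids=list(d.cell_ids))


def eb_batch_adjust(
    m: ExpressionMatrix,
    batch,
    clamp_negative: bool = False,
    allow_single_batch: bool = False,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location-scale batch adjustment.

    Per-gene batch means and variances (on data standardized by the pooled
    residual variance) are shrunk toward normal / inverse-gamma priors with
    method-of-moments hyperparameters and removed.  Genes with zero total
    variance pass through unchanged.  Negative adjusted values are optionally
    clamped to zero.
    """
    if m.unit != "E":
        raise ValueError("eb_batch_adjust expects an E-unit matrix")
    batch = pd.Series(batch)
    if list(batch.index) != list(m.cells):
        if len(batch) == m.n_cells:
            batch.index = m.cells
        else:
            raise ValueError("batch vector does not align with matrix cells")
    levels = sorted(batch.unique())
    if len(levels) < 2:
        if allow_single_batch:
            return m.copy()
        raise ValueError("need at least 2 batches (or allow_single_batch=True)")
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"batch {bad!r} has fewer than 2 cells")

    X = m.values.to_numpy(dtype=float)
    n_genes, n_cells = X.shape
    groups = [np.asarray(batch == lv) for lv in levels]
    n_b = np.array([g.sum() for g in groups], dtype=float)

    total_var = X.var(axis=1)
    active = total_var > 1e-300
    out = X.copy()
    if active.any():
        Xa = X[active]
        batch_mean = np.stack([Xa[:, g].mean(axis=1) for g in groups])  # B x G
        grand_mean = (n_b[:, None] * batch_mean).sum(axis=0) / n_cells
        resid = Xa.copy()
        for bm, g in zip(batch_mean, groups):
            resid[:, g] -= bm[:, None]
        var_pooled = (resid**2).sum(axis=1) / n_cells
        var_pooled = np.maximum(var_pooled, 1e-12)
        sd = np.sqrt(var_pooled)
        S = (Xa - grand_mean[:, None]) / sd[:, None]

        gamma_hat = np.stack([S[:, g].mean(axis=1) for g in groups])
        delta_hat = np.stack([S[:, g].var(axis=1, ddof=1) for g in groups])

        adj = np.empty_like(S)
        for bi, g in enumerate(groups):
            gh, dh = gamma_hat[bi], delta_hat[bi]
            g_bar, t2 = gh.mean(), gh.var(ddof=1) if gh.size > 1 else 0.0
            d_mean, d_var = dh.mean(), dh.var(ddof=1) if dh.size > 1 else 0.0
            degenerate = d_var < 1e-12 or t2 < 1e-12
            if degenerate:
                # no information to pool across genes: use the per-batch
                # estimates directly (exact removal in the noise-free limit)
                g_star = gh
                d_star = np.maximum(dh, 1e-12)
            else:
                a_prior = (2.0 * d_var + d_mean**2) / d_var
                b_prior = (d_mean * d_var + d_mean**3) / d_var
                nb = n_b[bi]
                g_old, d_old = gh.copy(), dh.copy()
                for _ in range(max_iter):
                    g_new = (t2 * nb * gh + d_old * g_bar) / (t2 * nb + d_old)
                    sum2 = ((S[:, g] - g_new[:, None]) ** 2).sum(axis=1)
                    d_new = (0.5 * sum2 + b_prior) / (nb / 2.0 + a_prior - 1.0)
                    change = max(
                        np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                        np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
                    )
                    g_old, d_old = g_new, d_new
                    if change < tol:
                        break
                g_star, d_star = g_old, np.maximum(d_old, 1e-12)
            adj[:, g] = (S[:, g] - g_star[:, None]) / np.sqrt(d_star)[:, None]
        out[active] = adj * sd[:, None] + grand_mean[:, None]
    if clamp_negative:
        out = np.maximum(out, 0.0)
    return ExpressionMatrix(pd.DataFrame(out, index=m.genes, columns=m.cells), "E")


def ward_cluster(
    e: Embedding,
    n_coords: int = 4,
    k_candidates=range(2, 9),
) -> ClusterResult:
    """Ward (D2) hierarchical clustering on the leading principal coordinates.

    For each candidate k the dendrogram is cut and the mean silhouette
    computed on the same coordinates; the k with the highest mean silhouette
    wins (smallest k on ties).  Labels are renumbered so that cluster 1 is the
    largest, matching the convention of naming the dominant population first.
    """
    if n_coords > e.coords.shape[1]:
        raise ValueError("n_coords exceeds the embedding dimension")
    X = e.coords[:, :n_coords]
    n = X.shape[0]
    candidates = [k for k in k_candidates if 2 <= k < n]
    if not candidates:
        raise ValueError("no valid candidate k for this sample size")
    if len(candidates) < len(list(k_candidates)):
        warnings.warn("candidate k range truncated to the number of cells", stacklevel=2)
    Z = linkage(X, method="ward")
    sil = {}
    labels_by_k = {}
    for k in candidates:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, lab))
    best_k = max(sorted(sil), key=lambda k: (sil[k], -k))
    labels = labels_by_k[best_k]
    # relabel clusters by decreasing size (stable tie-break on old label)
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels])
    return ClusterResult(
        labels=labels,
        k=len(np.unique(labels)),
        silhouette_by_k=sil,
        linkage=Z,
        cell_ids=list(e.cell_ids),
    )
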