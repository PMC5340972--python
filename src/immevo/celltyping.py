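"""Marker-score cell typing, cluster differential expression, and signatures.

Cell identities are assigned from small literature-derived marker panels
(T: cd4/cd8a/cd8b/cd28/ctla4; NK-like: nitr/dicp/nk-lysin family members;
myeloid: spi1b): the score of a panel is the mean log2(TPM+1) over its genes,
and a cell is labelled with the unique panel whose score exceeds 1 (cells with
zero or several panels above threshold stay unassigned).

Differential expression between a cluster and the rest uses a dropout-aware
two-part statistic: a Fisher exact test on detection rates combined, by
Stouffer weighting, with a rank-sum test on positive expression values; the
per-gene z is Holm-adjusted across genes and mapped back to the z scale.
Genes with log2 fold-change > 2 and adjusted z > 3 form the extended
cell-type signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fisher_exact_test, rank_sum_test, holm_adjust_z, stouffer_combine
from .matrix import ExpressionMatrix

__all__ = [
    "DEFAULT_MARKER_SETS",
    "MarkerSets",
    "SignatureSet",
    "marker_score",
    "assign_identity",
    "differential_expression",
    "build_signatures",
    "signature_score",
    "cross_species_enrichment",
    "ssc_comparison",
    "expression_heatmap",
]

# literature marker panels; the nitr/dicp/nkl entries are family prefixes
# expanded against the matrix gene ids
DEFAULT_MARKER_SETS = {
    "T": ["cd4", "cd8a", "cd8b", "cd28", "ctla4"],
    "NK-like": ["nitr*", "dicp*", "nkl*"],
    "myeloid": ["spi1b"],
}

MARKER_DISPLAY_TPM = 5.0  # binary "expresses gene X" display threshold


@dataclass
class MarkerSets:
    """Named marker panels; overlapping panels are allowed with a warning."""

    sets: dict

    def __post_init__(self) -> None:
        if not self.sets or any(len(v) == 0 for v in self.sets.values()):
            raise ValueError("marker sets must be nonempty")
        seen: dict[str, str] = {}
        for name, genes in self.sets.items():
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"marker {g!r} appears in both {seen[g]!r} and {name!r}",
                        stacklevel=2,
                    )
                seen[g] = name

    def expand(self, gene_ids: Iterable[str]) -> dict:
        """Resolve ``prefix*`` family patterns against the matrix gene ids."""
        gene_ids = list(gene_ids)
        out = {}
        for name, genes in self.sets.items():
            members = []
            for g in genes:
                if g.endswith("*"):
                    members.extend(x for x in gene_ids if x.startswith(g[:-1]))
                elif g in gene_ids:
                    members.append(g)
                else:
                    warnings.warn(f"marker gene {g!r} absent from matrix", stacklevel=2)
            out[name] = members
        return out


def marker_score(m: ExpressionMatrix, sets: MarkerSets | Mapping) -> pd.DataFrame:
    """Cell x type score table: mean E over each panel's present genes."""
    if m.unit != "E":
        raise ValueError("marker_score expects an E-unit matrix")
    if not isinstance(sets, MarkerSets):
        sets = MarkerSets(dict(sets))
    expanded = sets.expand(m.genes)
    scores = {}
    for name, genes in expanded.items():
        if not genes:
            raise ValueError(f"marker set {name!r} has no genes present in the matrix")
        scores[name] = m.values.loc[genes].mean(axis=0)
    return pd.DataFrame(scores, index=m.cells)


def assign_identity(scores: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Label each cell with the unique panel scoring strictly above threshold.

    Zero or more-than-one panels above threshold leaves the cell unassigned.
    """
    above = scores.to_numpy() > threshold
    labels = []
    cols = list(scores.columns)
    for row in above:
        hits = np.nonzero(row)[0]
        labels.append(cols[hits[0]] if hits.size == 1 else "unassigned")
    return pd.Series(labels, index=scores.index, name="identity")


def differential_expression(
    m: ExpressionMatrix,
    labels,
    group: str,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Group-vs-rest differential expression with a two-part dropout-aware z.

    Input must be a TPM matrix.  Per gene: log2 fold-change of group mean TPM
    (pseudocount 1), a detection-rate Fisher exact component and a rank-sum
    component on positive log values combined via Stouffer weighting, then
    Holm adjustment mapped back to z.

    Returns a DataFrame indexed by gene with columns log2_fc, z, z_adj, p,
    p_adj, detect_frac_in, detect_frac_out.
    """
    if m.unit != "TPM":
        raise ValueError("differential_expression expects a TPM matrix")
    labels = pd.Series(labels)
    if len(labels) == m.n_cells and list(labels.index) != list(m.cells):
        labels.index = m.cells
    in_mask = (labels.loc[m.cells] == group).to_numpy()
    out_mask = ~in_mask
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    if n_in < min_cells or n_out < min_cells:
        raise ValueError(f"each group needs >= {min_cells} cells (got {n_in} vs {n_out})")
    X = m.values.to_numpy(dtype=float)
    E = np.log2(X + 1.0)
    rows = []
    for gi in range(X.shape[0]):
        x_in, x_out = X[gi, in_mask], X[gi, out_mask]
        det_in, det_out = x_in > 0, x_out > 0
        k_in, k_out = int(det_in.sum()), int(det_out.sum())
        fc = float(np.log2((x_in.mean() + 1.0) / (x_out.mean() + 1.0)))
        # detection component
        if k_in == k_out == 0 or (k_in == n_in and k_out == n_out):
            z_det = np.nan if (k_in == 0 and k_out == 0) else 0.0
        else:
            p_det = fisher_exact_test(
                [[k_in, n_in - k_in], [k_out, n_out - k_out]]
            ).pvalue
            mag = stats.norm.isf(min(max(p_det, 1e-300), 1.0) / 2.0)
            z_det = float(np.sign(k_in / n_in - k_out / n_out) * max(mag, 0.0))
        # positive-values component
        e_in, e_out = E[gi, in_mask][det_in], E[gi, out_mask][det_out]
        if e_in.size >= 2 and e_out.size >= 2:
            res = rank_sum_test(e_in, e_out)
            mag = stats.norm.isf(min(max(res.pvalue, 1e-300), 1.0) / 2.0)
            mean_diff = e_in.mean() - e_out.mean()
            z_pos = float(np.sign(mean_diff) * max(mag, 0.0)) if mean_diff != 0 else 0.0
        else:
            z_pos = np.nan
        z = stouffer_combine([z_det, z_pos])
        rows.append(
            {
                "log2_fc": fc,
                "z": z,
                "detect_frac_in": k_in / n_in,
                "detect_frac_out": k_out / n_out,
            }
        )
    de = pd.DataFrame(rows, index=m.genes)
    p_raw, p_adj, z_adj = holm_adjust_z(de["z"].to_numpy())
    de["p"] = p_raw
    de["p_adj"] = p_adj
    de["z_adj"] = z_adj
    return de


@dataclass
class SignatureSet:
    """Ranked per-type gene lists with (log2_fc, adjusted z) provenance."""

    signatures: dict  # type -> DataFrame(log2_fc, z_adj) indexed by gene, fc-descending

    def genes(self, name: str) -> list[str]:
        return list(self.signatures[name].index)


def build_signatures(
    de_by_type: Mapping[str, pd.DataFrame],
    fc_min: float = 2.0,
    adjz_min: float = 3.0,
) -> SignatureSet:
    """Extended signatures: genes with log2 FC > fc_min and adjusted z > adjz_min.

    Thresholds are strict; genes qualifying for two or more types are dropped
    from all (signatures stay disjoint).  An empty signature is a warning.
    """
    raw = {}
    for name, de in de_by_type.items():
        sel = de[(de["log2_fc"] > fc_min) & (de["z_adj"] > adjz_min)]
        raw[name] = sel.sort_values(["log2_fc"], ascending=False, kind="stable")
    counts: dict[str, int] = {}
    for sel in raw.values():
        for g in sel.index:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c > 1}
    out = {}
    for name, sel in raw.items():
        sel = sel.loc[[g for g in sel.index if g not in shared], ["log2_fc", "z_adj"]]
        if sel.empty:
            warnings.warn(f"signature for {name!r} is empty", stacklevel=2)
        out[name] = sel
    return SignatureSet(signatures=out)


def signature_score(m: ExpressionMatrix, sig: SignatureSet) -> pd.DataFrame:
    """Mean E over signature genes per cell, min-max standardized to [0, 1].

    If every cell has the same raw score for a signature, the standardized
    score is defined as 0 for all cells.
    """
    if m.unit != "E":
        raise ValueError("signature_score expects an E-unit matrix")
    out = {}
    for name, table in sig.signatures.items():
        genes = [g for g in table.index if g in m.genes]
        if not genes:
            raise ValueError(f"signature {name!r} has no genes present in the matrix")
        raw = m.values.loc[genes].mean(axis=0)
        lo, hi = raw.min(), raw.max()
        out[name] = (raw - lo) / (hi - lo) if hi > lo else raw * 0.0
    return pd.DataFrame(out, index=m.cells)


def cross_species_enrichment(
    de_genes: Iterable[str],
    background_genes: Iterable[str],
    signature: Iterable[str],
    ortholog_map: Mapping[str, Iterable[str]] | None = None,
) -> dict:
    """Fisher exact enrichment of a human signature among cluster DE genes.

    A gene counts as "in signature" when it (or any of its mapped orthologs)
    belongs to the signature gene set.  Returns the 2x2 table, the sample odds
    ratio, and the two-sided Fisher p; degenerate margins give p = 1 with the
    odds ratio flagged undefined.
    """
    de_genes = set(de_genes)
    background_genes = set(background_genes)
    if de_genes & background_genes:
        raise ValueError("DE and background gene sets must be disjoint")
    signature = set(signature)

    def in_sig(g: str) -> bool:
        if ortholog_map is None:
            return g in signature
        return any(o in signature for o in ortholog_map.get(g, ()))

    a = sum(in_sig(g) for g in de_genes)
    b = len(de_genes) - a
    c = sum(in_sig(g) for g in background_genes)
    d = len(background_genes) - c
    res = fisher_exact_test([[a, b], [c, d]])
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": res.statistic,
        "p": res.pvalue,
        "flag": res.flag,
    }


def ssc_comparison(ssc, labels, one_vs_rest: bool = True) -> pd.DataFrame:
    """Percent difference of SSC medians and rank-sum p per cluster pair.

    Rows: each ordered pair (a, b) of distinct cluster labels with
    pct_diff = (median_a / median_b - 1) * 100, plus (optionally) each label
    vs the union of the others.  A zero median denominator is flagged.
    """
    ssc = pd.Series(ssc, dtype=float)
    labels = pd.Series(labels)
    if len(labels) != len(ssc):
        raise ValueError("ssc and labels length mismatch")
    labels.index = ssc.index
    rows = []
    groups = sorted(labels.unique())

    def compare(name_a, name_b, va, vb):
        if len(va) < 2 or len(vb) < 2:
            return
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        flag = None
        if med_b == 0:
            pct = float("nan")
            flag = "zero median denominator"
        else:
            pct = (med_a / med_b - 1.0) * 100.0
        res = rank_sum_test(va, vb)
        rows.append(
            {
                "group_a": name_a,
                "group_b": name_b,
                "pct_diff": pct,
                "p": res.pvalue,
                "flag": flag,
            }
        )

    for a in groups:
        for b in groups:
            if a == b:
                continue
            compare(a, b, ssc[labels == a].to_numpy(), ssc[labels == b].to_numpy())
    if one_vs_rest and len(groups) > 2:
        for a in groups:
            compare(a, "rest", ssc[labels == a].to_numpy(), ssc[labels != a].to_numpy())
    return pd.DataFrame(rows)


def expression_heatmap(m: ExpressionMatrix, genes, labels, path) -> None:
    """Basic matrix plot of selected genes x cells grouped by cluster label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = pd.Series(labels)
    labels.index = m.cells
    order = labels.sort_values(kind="stable").index
    genes = [g for g in genes if g in m.genes]
    data = m.values.loc[genes, order]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.2 * len(genes))))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(genes)), genes, fontsize=6)
    ax.set_xlabel("cells (grouped by cluster)")
    fig.colorbar(im, ax=ax, label=m.unit)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
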