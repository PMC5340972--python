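"""Cross-species conservation statistics for cell-type-specific genes.

Signature genes are derived from bulk immune-cell expression with an
empirical-Bayes moderated t (per-gene variances shrunk toward a common prior;
prior df and scale by method of moments), Benjamini-Hochberg adjusted p < 0.01,
ranked by fold-change, top-100 unique per type.  Conservation is compared
between gene sets as the proportion of genes with orthologs per species
(permutation null over set-membership labels, add-one p estimator), globally
across species with a paired Wilcoxon signed-rank test, and on conserved genes
via rank-sum tests on average percent sequence identity and on one-to-one
ortholog dN/dS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats, special
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_test, signed_rank_test
from .matrix import ExpressionMatrix

__all__ = [
    "SignatureDerivationConfig",
    "derive_signature_genes",
    "moderated_t_test",
    "ortholog_proportion",
    "permutation_test_proportions",
    "paired_wilcoxon_across_species",
    "identity_comparison",
    "dnds_comparison",
    "zebrafish_de_gene_sets",
    "expression_matched_background",
]


@dataclass
class SignatureDerivationConfig:
    """Bulk-signature derivation parameters.

    ``prefilter_threshold``: minimum max-group-mean normalized expression
    (5 for the mouse arrays, 8 for the human arrays); ``merge_map`` folds
    subtypes into groups (CD4/CD8 -> T, monocyte/granulocyte -> myeloid).
    """

    prefilter_threshold: float = 5.0
    merge_map: Mapping[str, str] | None = None
    adj_p_cutoff: float = 0.01
    top_n: int = 100

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0.0 < self.adj_p_cutoff < 1.0:
            raise ValueError("adj_p_cutoff must be in (0, 1)")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return float("inf")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """EB shrinkage of per-gene variances toward a common prior.

    Method-of-moments fit of a scaled inverse chi-square prior on the log
    scale.  Returns (posterior variances, prior df d0, prior scale s0^2);
    d0 = inf means complete pooling.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(float(e_var))
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = float("inf")
        s02 = float(np.exp(e_mean))
        post = np.full_like(s2, s02)
    return post, d0, s02


def moderated_t_test(
    x: np.ndarray,
    y: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-row two-sample moderated t between column groups x and y.

    ``prior_df`` overrides the estimated prior df (0 recovers the ordinary
    two-sample pooled t).  Returns log-fc (mean difference), t, p, df.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    df = n1 + n2 - 2
    diff = x.mean(axis=1) - y.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    if prior_df is None:
        s2_post, d0, _ = _squeeze_var(s2, df)
    elif prior_df == 0:
        s2_post, d0 = s2, 0.0
    else:
        _, _, s02 = _squeeze_var(s2, df)
        d0 = prior_df
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    se = np.sqrt(np.maximum(s2_post, 1e-300) * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    total_df = df + d0 if np.isfinite(d0) else 1e6
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame({"diff": diff, "t": t, "p": p, "df": total_df})


def derive_signature_genes(
    bulk: pd.DataFrame,
    group_labels,
    cfg: SignatureDerivationConfig,
) -> dict:
    """Top-N unique signature genes per merged group from bulk expression.

    ``bulk`` is genes x samples (normalized log-scale expression);
    ``group_labels`` one label per sample.  Genes are prefiltered by maximum
    group mean, tested group-vs-rest with the moderated t, BH-adjusted,
    ranked by fold-change, and the per-type top-N lists are made disjoint.
    """
    labels = pd.Series(group_labels)
    if len(labels) != bulk.shape[1]:
        raise ValueError("one group label per sample required")
    labels.index = bulk.columns
    if cfg.merge_map:
        labels = labels.map(lambda g: cfg.merge_map.get(g, g))
    groups = sorted(labels.unique())
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    group_means = pd.DataFrame({g: bulk.loc[:, labels == g].mean(axis=1) for g in groups})
    kept = bulk.loc[group_means.max(axis=1) >= cfg.prefilter_threshold]
    raw_top = {}
    for g in groups:
        x = kept.loc[:, labels == g].to_numpy()
        y = kept.loc[:, labels != g].to_numpy()
        res = moderated_t_test(x, y)
        res.index = kept.index
        _, p_adj, _, _ = multipletests(res["p"], method="fdr_bh")
        res["p_adj"] = p_adj
        sig = res[(res["p_adj"] < cfg.adj_p_cutoff) & (res["diff"] > 0)]
        if sig.empty:
            warnings.warn(f"no significant genes for group {g!r}", stacklevel=2)
        sig = sig.sort_values("diff", ascending=False, kind="stable")
        raw_top[g] = sig.head(cfg.top_n)
    counts: dict[str, int] = {}
    for table in raw_top.values():
        for gene in table.index:
            counts[gene] = counts.get(gene, 0) + 1
    shared = {gene for gene, c in counts.items() if c > 1}
    return {
        g: table.loc[[gene for gene in table.index if gene not in shared]]
        for g, table in raw_top.items()
    }


# ---------------------------------------------------------------------------
# conservation statistics


def _ortholog_flags(genes: Iterable[str], table: pd.DataFrame, species: str) -> np.ndarray:
    col = f"ortholog_{species}"
    if col not in table.columns:
        raise ValueError(f"no ortholog column for species {species!r}")
    genes = list(genes)
    present = [g for g in genes if g in table.index]
    missing = len(genes) - len(present)
    if missing:
        warnings.warn(f"{missing} genes absent from the annotation table", stacklevel=3)
    if not present:
        raise ValueError("no evaluable genes in the annotation table")
    return table.loc[present, col].to_numpy(dtype=bool)


def ortholog_proportion(genes: Iterable[str], table: pd.DataFrame, species: str) -> float:
    """Fraction of evaluated genes with an ortholog in the given species."""
    flags = _ortholog_flags(genes, table, species)
    return float(flags.mean())


def permutation_test_proportions(
    set_a: Iterable[str],
    set_b: Iterable[str],
    table: pd.DataFrame,
    species: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation test of the ortholog-proportion difference between two sets.

    Null: set membership labels are permuted over the pooled genes.  Two-sided
    p uses the add-one estimator (1 + #{|null| >= |obs|}) / (1 + n_perm), so
    a saturated result reports 1/(1+n_perm), never zero.
    """
    set_a, set_b = list(set_a), list(set_b)
    if set(set_a) & set(set_b):
        raise ValueError("gene sets must be disjoint")
    if len(set_a) < 5 or len(set_b) < 5:
        raise ValueError("each set needs at least 5 genes")
    fa = _ortholog_flags(set_a, table, species)
    fb = _ortholog_flags(set_b, table, species)
    obs = fa.mean() - fb.mean()
    pooled = np.concatenate([fa, fb]).astype(float)
    na = fa.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        stat = pooled[:na].mean() - pooled[na:].mean()
        if abs(stat) >= abs(obs) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return {
        "proportion_a": float(fa.mean()),
        "proportion_b": float(fb.mean()),
        "difference": float(obs),
        "p": float(p),
        "n_perm": n_perm,
    }


def paired_wilcoxon_across_species(
    props_a: Sequence[float],
    props_b: Sequence[float],
) -> dict:
    """Paired Wilcoxon signed-rank test on per-species proportion differences."""
    a = np.asarray(props_a, dtype=float)
    b = np.asarray(props_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 species pairs")
    res = signed_rank_test(a, b)
    return {"statistic": res.statistic, "p": res.pvalue, "exact": res.exact}


def _values_for(genes, table, column) -> np.ndarray:
    genes = [g for g in genes if g in table.index]
    vals = table.loc[genes, column].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def identity_comparison(
    set_a: Iterable[str],
    set_b: Iterable[str],
    table: pd.DataFrame,
    species: str,
) -> dict:
    """Rank-sum comparison of average % sequence identity of conserved genes."""
    va = _values_for(set_a, table, f"identity_{species}")
    vb = _values_for(set_b, table, f"identity_{species}")
    if va.size < 2 or vb.size < 2:
        raise ValueError("each set needs at least 2 conserved genes")
    res = rank_sum_test(va, vb)
    return {
        "median_a": float(np.median(va)),
        "median_b": float(np.median(vb)),
        "n_a": int(va.size),
        "n_b": int(vb.size),
        "p": res.pvalue,
    }


def dnds_comparison(set_a: Iterable[str], set_b: Iterable[str], table: pd.DataFrame) -> dict:
    """Rank-sum comparison of one-to-one ortholog dN/dS between gene sets."""
    va = _values_for(set_a, table, "dnds")
    vb = _values_for(set_b, table, "dnds")
    if va.size < 2 or vb.size < 2:
        raise ValueError("each set needs at least 2 genes with dN/dS")
    res = rank_sum_test(va, vb)
    return {
        "median_a": float(np.median(va)),
        "median_b": float(np.median(vb)),
        "n_a": int(va.size),
        "n_b": int(vb.size),
        "p": res.pvalue,
    }


def zebrafish_de_gene_sets(
    de_by_cluster: Mapping[str, pd.DataFrame],
    z_min: float = 1.0,
    top_n: int = 100,
) -> dict:
    """Per cluster: filter z > z_min, sort by fold-change, take the top N.

    Deterministic tie-break on gene id.  Fewer than top_n qualifying genes is
    a warning, not an error.
    """
    out = {}
    for cluster, de in de_by_cluster.items():
        sel = de[de["z"] > z_min]
        # stable sort on fold-change after ordering the index implements the
        # documented gene-id tie-break
        sel = sel.loc[sorted(sel.index)].sort_values(
            "log2_fc", ascending=False, kind="stable"
        )
        if len(sel) < top_n:
            warnings.warn(
                f"cluster {cluster!r}: only {len(sel)} genes pass z > {z_min}",
                stacklevel=2,
            )
        out[cluster] = list(sel.head(top_n).index)
    return out


def expression_matched_background(
    m: ExpressionMatrix,
    de_gene_sets: Mapping[str, Iterable[str]],
) -> set[str]:
    """Non-DE genes at or above the global mean expression level.

    The global mean is the mean of per-gene mean E across cells, recomputed on
    the input matrix; lowly expressed genes are excluded so that background
    conservation is compared at matched expression.
    """
    if m.unit != "E":
        raise ValueError("expression_matched_background expects an E-unit matrix")
    de_genes: set[str] = set()
    for genes in de_gene_sets.values():
        de_genes |= set(genes)
    gene_means = m.values.mean(axis=1)
    global_mean = float(gene_means.mean())
    return set(gene_means.index[(gene_means >= global_mean)]) - de_genes
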