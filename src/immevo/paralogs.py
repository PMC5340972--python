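"""Paralog duplication-age and expression-divergence (neofunctionalization) analysis.

Zebrafish paralog pairs carry the taxon of the duplication node from a Compara
gene-tree export.  Pairs are split into "recent" duplications (ray-finned fish
lineage: Actinopterygii or any of its child nodes) and "early" duplications
(bony vertebrates, Euteleostomi, or older).  Each gene is then assigned an
expression-pattern label from the single-cell clusters (specific to one
cluster, depleted from one cluster, ubiquitous, or uninformative), and pairs
are classified as expression-conserved or diverged; the diverged fraction is
the neofunctionalization rate per age class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "RECENT_TAXA",
    "EARLY_TAXA",
    "PATTERN_LABELS",
    "classify_duplication_age",
    "exclude_overlap_genes",
    "detected_genes",
    "assign_expression_patterns",
    "classify_pairs",
    "PairClassification",
]

# duplication-node taxa: ray-finned fish and child nodes => recent;
# bony vertebrates and parent taxa => early
RECENT_TAXA = frozenset(
    {"Actinopterygii", "Neopterygii", "Otophysa", "Clupeocephala", "Danio rerio"}
)
EARLY_TAXA = frozenset({"Euteleostomi", "Bilateria", "Chordata", "Vertebrata"})

CLUSTERS = ("C1", "C2", "C3")
MAJOR_CLUSTERS = ("C1", "C2")
PATTERN_LABELS = tuple(
    [f"{c}-specific" for c in CLUSTERS]
    + [f"{c}-depleted" for c in CLUSTERS]
    + ["ubiquitous", "none"]
)


def classify_duplication_age(taxon: str) -> str:
    """Map a duplication-node taxon label to 'recent' or 'early'."""
    if taxon in RECENT_TAXA:
        return "recent"
    if taxon in EARLY_TAXA:
        return "early"
    raise ValueError(f"unknown duplication-node taxon: {taxon!r}")


def exclude_overlap_genes(pairs: pd.DataFrame) -> tuple[set[str], set[str], set[str]]:
    """Split genes into recent-only and early-only sets, dropping the overlap.

    ``pairs`` needs columns gene_a, gene_b, taxon.  Genes that participate in
    both a recent and an early duplication are excluded from both sets.
    Returns (recent_only, early_only, overlap).
    """
    recent: set[str] = set()
    early: set[str] = set()
    for _, row in pairs.iterrows():
        age = classify_duplication_age(row["taxon"])
        target = recent if age == "recent" else early
        target.add(row["gene_a"])
        target.add(row["gene_b"])
    overlap = recent & early
    return recent - overlap, early - overlap, overlap


def detected_genes(m: ExpressionMatrix, min_frac: float = 0.01) -> set[str]:
    """Genes with >0 TPM in at least ``ceil(min_frac * n_cells)`` cells."""
    if m.unit != "TPM":
        raise ValueError("detected_genes expects a TPM matrix")
    need = math.ceil(min_frac * m.n_cells)
    n_pos = (m.values.to_numpy() > 0).sum(axis=1)
    return set(m.genes[n_pos >= need])


def assign_expression_patterns(
    genes: Iterable[str],
    specific_sets: Mapping[str, Iterable[str]],
    depleted_sets: Mapping[str, Iterable[str]],
    detection_frac: pd.DataFrame,
    min_frac: float = 0.10,
) -> pd.Series:
    """Assign one expression-pattern label per gene.

    Precedence: cluster-specific (member of a cluster's top differential list)
    > cluster-depleted (member of a reversed-contrast top list) > ubiquitous
    (detected in at least ``min_frac`` of the cells of every cluster) > none.
    ``detection_frac`` is genes x clusters (fraction of cells with TPM > 0).
    Top lists are expected disjoint across clusters; within a tier, the lowest
    cluster index wins deterministically.
    """
    spec = {c: set(specific_sets.get(c, ())) for c in CLUSTERS}
    depl = {c: set(depleted_sets.get(c, ())) for c in CLUSTERS}
    labels = {}
    for g in genes:
        hit = [c for c in CLUSTERS if g in spec[c]]
        if len(hit) > 1:
            raise AssertionError(f"gene {g} in multiple cluster-specific top lists")
        if hit:
            labels[g] = f"{hit[0]}-specific"
            continue
        hit = [c for c in CLUSTERS if g in depl[c]]
        if hit:
            labels[g] = f"{hit[0]}-depleted"
            continue
        if g in detection_frac.index and (detection_frac.loc[g, list(CLUSTERS)] >= min_frac).all():
            labels[g] = "ubiquitous"
        else:
            labels[g] = "none"
    return pd.Series(labels, name="pattern")


def _informative(label: str) -> bool:
    return label not in ("none",)


def _major_specific_or_depleted(label: str) -> bool:
    return label in {f"{c}-specific" for c in MAJOR_CLUSTERS} | {
        f"{c}-depleted" for c in MAJOR_CLUSTERS
    }


@dataclass
class PairClassification:
    """Per-pair expression-conservation classification and per-age-class rates."""

    table: pd.DataFrame
    rates: dict = field(default_factory=dict)

    def rate(self, age_class: str) -> float:
        """Neofunctionalization percentage for an age class ('recent'/'early'/'all')."""
        r = self.rates[age_class]
        total = r["diverged"] + r["conserved"]
        return 100.0 * r["diverged"] / total if total else float("nan")


def classify_pairs(pairs: pd.DataFrame, patterns: Mapping[str, str]) -> PairClassification:
    """Classify paralog pairs as expression-conserved vs diverged.

    Rules: pairs where either gene has pattern "none" are excluded
    (uninformative); pairs where both genes are ubiquitous are excluded;
    a ubiquitous + non-ubiquitous pair is kept only when the other gene is
    specific to, or depleted from, one of the two major clusters (C1/C2).
    Remaining pairs are conserved when both labels agree, diverged otherwise.
    """
    rows = []
    for _, row in pairs.iterrows():
        a, b = sorted((row["gene_a"], row["gene_b"]))
        la = patterns.get(a, "none")
        lb = patterns.get(b, "none")
        age = classify_duplication_age(row["taxon"])
        if not (_informative(la) and _informative(lb)):
            status = "excluded_uninformative"
        elif la == "ubiquitous" and lb == "ubiquitous":
            status = "excluded_both_ubiquitous"
        elif "ubiquitous" in (la, lb):
            other = lb if la == "ubiquitous" else la
            status = "diverged" if _major_specific_or_depleted(other) else "excluded_minor_cluster"
        else:
            status = "conserved" if la == lb else "diverged"
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "taxon": row["taxon"],
                "age_class": age,
                "pattern_a": la,
                "pattern_b": lb,
                "status": status,
            }
        )
    table = pd.DataFrame(rows)
    rates = {}
    for age in ("recent", "early", "all"):
        sub = table if age == "all" else table[table["age_class"] == age]
        rates[age] = {
            "diverged": int((sub["status"] == "diverged").sum()),
            "conserved": int((sub["status"] == "conserved").sum()),
            "excluded": int(sub["status"].str.startswith("excluded").sum()),
        }
    return PairClassification(table=table, rates=rates)
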