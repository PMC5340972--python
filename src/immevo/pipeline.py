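"""End-to-end pipeline orchestration with seed fan-out and a JSON run report.

Stages (each toggleable): synthetic data generation, QC, batch adjustment +
MDS + Ward clustering, marker-score cell typing + DE + signatures, per-cell
V(D)J detection, conservation statistics on annotation tables, and paralog
expression-divergence classification.  All randomness flows from a single
global seed through named substreams, so a fixed config yields an identical
report (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltyping, cluster, conservation, paralogs, qc, synthetic, vdj

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("qc", "cluster", "celltype", "vdj", "conservation", "paralogs")


@dataclass
class RunConfig:
    """Pipeline configuration; every stage parameter defaults to the
    analysis' standard value (QC 500 genes / 10,000 reads, 4 principal
    coordinates, marker score > 1, signature FC > 2 and adjusted z > 3,
    reference pads 20/7/50, V(D)J filters 90/90/90, top-100 DE with z > 1,
    10,000 permutations, 1% detection and 10% ubiquity fractions, 5 TPM
    display threshold)."""

    seed: int = 0
    outdir: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    synthetic: dict = field(default_factory=dict)
    min_genes: int = 500
    min_reads: int = 10_000
    n_coords: int = 4
    k_candidates: tuple = (2, 3, 4, 5, 6, 7, 8)
    marker_threshold: float = 1.0
    fc_min: float = 2.0
    adjz_min: float = 3.0
    vdj_cells: int = 40  # cap on cells given read sets (runtime control)
    n_v: int = 4
    n_j: int = 3
    read_len: int = 50
    n_vdj_reads: int = 50
    n_background_reads: int = 100
    read_error_rate: float = 0.01
    n_perm: int = 2000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown config fields: {bad}")
        cfg = cls(**raw)
        bad_stages = sorted(set(cfg.stages) - set(STAGES))
        if bad_stages:
            raise ValueError(f"unknown stages: {bad_stages}")
        return cfg


def _substream_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES) + 1)
    names = ("synthetic",) + STAGES
    return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report.

    Any stage failure is re-raised with the stage name attached.  When
    ``config.outdir`` is set, stage artifacts (matrices, labels, calls,
    tables) are written there along with ``report.json``.
    """
    t0 = time.time()
    seeds = _substream_seeds(config.seed)
    stages = {s: config.stages.get(s, True) for s in STAGES}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "substream_seeds": seeds, "stages": {}}

    def run_stage(name, fn):
        if not stages.get(name, True):
            return None
        try:
            result = fn()
        except Exception as exc:  # attach the failing stage's name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = result
        return result

    # --- synthetic inputs (always needed by downstream stages)
    syn_cfg = synthetic.SyntheticConfig(**{**config.synthetic, "seed": seeds["synthetic"]})
    dataset = synthetic.generate_expression_dataset(syn_cfg)
    report["stages"]["synthetic"] = {
        "n_cells": int(dataset.tpm.shape[1]),
        "n_genes": int(dataset.tpm.shape[0]),
        "population_sizes": dataset.cell_meta["true_type"].value_counts().to_dict(),
    }
    if outdir:
        synthetic.write_expression_dataset(dataset, outdir / "synthetic")

    state: dict = {"dataset": dataset}

    def stage_qc():
        m = dataset.tpm_matrix()
        reads = dataset.cell_meta["mapped_reads"]
        filtered, rep = qc.qc_filter(m, reads, config.min_genes, config.min_reads)
        state["tpm"] = filtered
        state["E"] = qc.log_transform(filtered)
        if outdir:
            rep.per_cell.to_csv(outdir / "qc_per_cell.tsv", sep="\t")
        return {
            "n_input": rep.n_input,
            "n_removed": rep.n_removed,
            "n_retained": rep.n_retained,
            "mean_detected_genes": rep.mean_detected_genes,
        }

    run_stage("qc", stage_qc)
    if "tpm" not in state:  # qc disabled
        state["tpm"] = dataset.tpm_matrix()
        state["E"] = qc.log_transform(state["tpm"])

    def stage_cluster():
        batch = dataset.cell_meta.loc[state["E"].cells, "batch"]
        adjusted = cluster.eb_batch_adjust(state["E"], batch, allow_single_batch=True)
        diss = cluster.pcc_dissimilarity(adjusted)
        emb = cluster.classical_mds(diss, k=max(config.n_coords, 4))
        res = cluster.ward_cluster(emb, n_coords=config.n_coords, k_candidates=config.k_candidates)
        state["adjusted"] = adjusted
        state["embedding"] = emb
        state["clusters"] = pd.Series(res.labels, index=state["E"].cells, name="cluster")
        if outdir:
            pd.DataFrame(
                emb.coords,
                index=state["E"].cells,
                columns=[f"PC{i + 1}" for i in range(emb.coords.shape[1])],
            ).to_csv(outdir / "embedding.tsv", sep="\t")
            state["clusters"].to_csv(outdir / "clusters.tsv", sep="\t")
        truth = dataset.cell_meta.loc[state["E"].cells, "true_type"]
        from sklearn.metrics import adjusted_rand_score

        return {
            "k": res.k,
            "silhouette_by_k": {int(k): v for k, v in res.silhouette_by_k.items()},
            "ari_vs_truth": float(adjusted_rand_score(truth, res.labels)),
            "cluster_sizes": pd.Series(res.labels).value_counts().to_dict(),
        }

    run_stage("cluster", stage_cluster)

    def stage_celltype():
        marker_sets = celltyping.MarkerSets(
            {
                name: list(dataset.gene_meta.index[dataset.gene_meta["marker_of"] == name])
                for name in syn_cfg.population_names
            }
        )
        scores = celltyping.marker_score(state["E"], marker_sets)
        ident = celltyping.assign_identity(scores, threshold=config.marker_threshold)
        truth = dataset.cell_meta.loc[ident.index, "true_type"]
        accuracy = float((ident == truth).mean())
        de_by_type = {}
        sig_info = {}
        if "clusters" in state:
            for c in sorted(state["clusters"].unique()):
                de_by_type[f"C{c}"] = celltyping.differential_expression(
                    state["tpm"], state["clusters"], c
                )
            sigs = celltyping.build_signatures(de_by_type, config.fc_min, config.adjz_min)
            sig_scores = celltyping.signature_score(state["E"], sigs)
            state["de_by_cluster"] = de_by_type
            state["signatures"] = sigs
            sig_info = {name: len(t) for name, t in sigs.signatures.items()}
            if outdir:
                sig_scores.to_csv(outdir / "signature_scores.tsv", sep="\t")
            ssc = celltyping.ssc_comparison(
                dataset.cell_meta.loc[ident.index, "ssc"], state["clusters"]
            )
            if outdir:
                ssc.to_csv(outdir / "ssc_comparison.tsv", sep="\t", index=False)
        state["identity"] = ident
        if outdir:
            scores.to_csv(outdir / "marker_scores.tsv", sep="\t")
            ident.to_csv(outdir / "identity.tsv", sep="\t")
        return {
            "assigned": ident.value_counts().to_dict(),
            "marker_accuracy": accuracy,
            "signature_sizes": sig_info,
        }

    run_stage("celltype", stage_celltype)

    def stage_vdj():
        segs = synthetic.generate_germline_segments(
            config.n_v, config.n_j, seed=seeds["vdj"]
        )
        # evenly spaced cells span all populations (cells are ordered by type)
        n_all = len(dataset.cell_meta)
        take = min(config.vdj_cells, n_all)
        idx = sorted(set(np.linspace(0, n_all - 1, take).round().astype(int)))
        cells = dataset.cell_meta.index[idx]
        sub = dataset.cell_meta.loc[cells]
        sub_ds = dataclasses.replace(dataset, cell_meta=sub)
        readsets = synthetic.generate_cell_reads(
            sub_ds,
            segs,
            read_len=config.read_len,
            n_background=config.n_background_reads,
            n_vdj=config.n_vdj_reads,
            error_rate=config.read_error_rate,
            seed=seeds["vdj"],
        )
        calls = vdj.detect_cell_vdj(readsets, segs)
        positive = pd.Series(
            {cid: any(c.passed for c in cs) for cid, cs in calls.items()}
        )
        truth = sub["has_vdj"]
        tp = int((positive & truth).sum())
        fp = int((positive & ~truth).sum())
        fn = int((~positive & truth).sum())
        tn = int((~positive & ~truth).sum())
        if outdir:
            vdj.calls_to_table(calls).to_csv(outdir / "vdj_calls.tsv", sep="\t", index=False)
        result = {
            "n_cells": int(len(cells)),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
        if "clusters" in state:
            shared = [c for c in cells if c in state["clusters"].index]
            if shared and positive.loc[shared].any():
                trbc_like = state["tpm"].values.loc[
                    dataset.gene_meta.index[dataset.gene_meta["marker_of"] == "T"][0]
                ]
                assoc = vdj.associate_vdj(
                    positive.loc[shared],
                    state["clusters"].loc[shared],
                    trbc_like.loc[shared],
                )
                result["p_cluster"] = assoc["p_cluster"]
                result["p_trbc1"] = assoc["p_trbc1"]
        return result

    run_stage("vdj", stage_vdj)

    def stage_conservation():
        props = {
            "T_TM": {"mouse": 0.76, "human": 0.76, "frog": 0.70, "lamprey": 0.30},
            "NK_TM": {"mouse": 0.36, "human": 0.36, "frog": 0.30, "lamprey": 0.10},
            "T_CN": {"mouse": 0.80, "human": 0.80, "frog": 0.75, "lamprey": 0.40},
            "NK_CN": {"mouse": 0.80, "human": 0.80, "frog": 0.75, "lamprey": 0.40},
        }
        table = synthetic.generate_annotation_tables(
            100,
            props,
            identity_means={"T_TM": 75.0, "NK_TM": 60.0, "T_CN": 78.0, "NK_CN": 78.0},
            dnds_means={"T_TM": 0.15, "NK_TM": 0.30, "T_CN": 0.12, "NK_CN": 0.12},
            seed=seeds["conservation"],
        )
        sets = {s: list(table.index[table["gene_set"] == s]) for s in props}
        perm = conservation.permutation_test_proportions(
            sets["T_TM"], sets["NK_TM"], table, "mouse",
            n_perm=config.n_perm, seed=seeds["conservation"],
        )
        species = ["mouse", "human", "frog", "lamprey"]
        pa = [conservation.ortholog_proportion(sets["T_TM"], table, sp) for sp in species]
        pb = [conservation.ortholog_proportion(sets["NK_TM"], table, sp) for sp in species]
        dnds = conservation.dnds_comparison(sets["T_TM"], sets["NK_TM"], table)
        if outdir:
            table.to_csv(outdir / "annotation_table.tsv", sep="\t")
        return {
            "tm_proportion_T": perm["proportion_a"],
            "tm_proportion_NK": perm["proportion_b"],
            "tm_permutation_p": perm["p"],
            "per_species_T": dict(zip(species, pa)),
            "per_species_NK": dict(zip(species, pb)),
            "dnds_p": dnds["p"],
        }

    run_stage("conservation", stage_conservation)

    def stage_paralogs():
        fams = synthetic.generate_paralog_families(seed=seeds["paralogs"])
        cls = paralogs.classify_pairs(fams.pairs, fams.planted_patterns)
        result = {
            "neofunctionalization_recent_pct": cls.rate("recent"),
            "neofunctionalization_early_pct": cls.rate("early"),
            "counts": cls.rates,
        }
        # expression-pattern route on the dataset genes (artifact output);
        # needs the three canonical clusters to be present
        if "de_by_cluster" in state and {"C1", "C2", "C3"} <= set(state["de_by_cluster"]):
            spec_sets = conservation.zebrafish_de_gene_sets(state["de_by_cluster"])
            # enforce disjointness across clusters (uniqueness rule, as for
            # signatures): genes in two top lists are dropped from all
            from collections import Counter

            seen = Counter(g for genes in spec_sets.values() for g in genes)
            spec_sets = {
                c: [g for g in genes if seen[g] == 1] for c, genes in spec_sets.items()
            }
            detect = pd.DataFrame(
                {
                    f"C{c}": (
                        state["tpm"].values.loc[:, state["clusters"] == c] > 0
                    ).mean(axis=1)
                    for c in sorted(state["clusters"].unique())
                }
            )
            patterns = paralogs.assign_expression_patterns(
                state["tpm"].genes, spec_sets, {}, detect
            )
            result["pattern_counts"] = patterns.value_counts().to_dict()
            if outdir:
                patterns.to_csv(outdir / "expression_patterns.tsv", sep="\t")
        if outdir:
            cls.table.to_csv(outdir / "paralog_pairs.tsv", sep="\t", index=False)
        return result

    run_stage("paralogs", stage_paralogs)

    report["elapsed_seconds"] = round(time.time() - t0, 2)
    if outdir:
        serializable = json.loads(json.dumps(report, default=str))
        (outdir / "report.json").write_text(json.dumps(serializable, indent=2))
    return report
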