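"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure of a FACS-sorted immune
single-cell RNA-seq study on a transgenic reporter line: three cell
populations (T, NK-like, myeloid-like) with planted marker genes and broader
expression programs, negative-binomial counts with logistic dropout and
per-batch shifts, TPM derived from counts and fixed per-gene effective
lengths, per-cell FACS side-scatter values, per-cell read sets containing one
recombined TCR-beta transcript for T cells, germline V/J segment sets,
BioMart-style orthology/identity/dN/dS annotation tables, and Compara-style
paralog-pair tables.

All generators are deterministic given their configuration and seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import revcomp, pairwise_identity
from .matrix import ExpressionMatrix, write_matrix_tsv, write_matrix_mtx
from .paralogs import RECENT_TAXA, EARLY_TAXA

__all__ = [
    "SyntheticConfig",
    "ExpressionDataset",
    "SegmentSet",
    "ReadSet",
    "ParalogFamilies",
    "largest_remainder",
    "generate_expression_dataset",
    "generate_germline_segments",
    "generate_cell_reads",
    "generate_annotation_tables",
    "generate_paralog_families",
    "write_expression_dataset",
    "write_segments_fasta",
    "write_readsets_fastq",
]

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# expression dataset


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic expression dataset.

    Defaults reflect the emulated study: 300 cells in three populations with
    proportions (0.65, 0.31, 0.04), two batches (fish), small marker panels
    plus broader per-type expression programs, negative-binomial counts with
    logistic dropout, and lognormal library sizes.
    """

    n_cells: int = 300
    population_proportions: tuple = (0.65, 0.31, 0.04)
    population_names: tuple = ("T", "NK-like", "myeloid")
    n_genes: int = 2000
    n_markers_per_type: int = 30
    n_program_genes_per_type: int = 150
    marker_high_mean: float = 60.0
    marker_baseline_mean: float = 0.02
    program_fold: float = 4.0
    n_batches: int = 2
    batch_shift_sd: float = 0.4  # log2-expression units
    dropout_midpoint: float = 1.0  # log2(1+mean) at 50% dropout
    dropout_slope: float = 1.0
    library_size_mean: float = 50_000.0  # reads mapped to transcripts
    library_size_sd: float = 10_000.0
    nb_dispersion: float = 0.4  # var = mu + dispersion * mu^2
    ssc_location_per_type: tuple = (100.0, 125.0, 330.0)  # arbitrary FACS units
    ssc_sd: float = 12.0
    vdj_fraction: float = 1.0  # fraction of T cells carrying one recombined transcript
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.population_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("population_proportions must sum to 1")
        if (props < 0).any():
            raise ValueError("population_proportions must be nonnegative")
        if len(props) != len(self.population_names):
            raise ValueError("one proportion per population name required")
        for name in ("n_cells", "n_genes", "n_markers_per_type", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_special = len(props) * (self.n_markers_per_type + self.n_program_genes_per_type)
        if n_special > self.n_genes:
            raise ValueError("n_genes too small for the requested marker/program genes")


@dataclass
class ExpressionDataset:
    """TPM + count matrices with per-cell and per-gene metadata.

    ``cell_meta`` columns: batch, true_type, ssc, mapped_reads, has_vdj.
    ``gene_meta`` columns: marker_of, program_of, eff_length.
    """

    tpm: pd.DataFrame
    counts: pd.DataFrame
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    config: SyntheticConfig

    def tpm_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.tpm.copy(), "TPM")

    def counts_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.counts.copy(), "counts")


def largest_remainder(n: int, proportions) -> np.ndarray:
    """Allocate ``n`` items to groups by the largest-remainder method.

    Ties in the fractional remainders are broken toward the earlier group
    index (stable sort), so the allocation is deterministic.
    """
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    left = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:left]] += 1
    return base


def generate_expression_dataset(config: SyntheticConfig) -> ExpressionDataset:
    """Generate the gene x cell TPM/count matrices and metadata.

    Marker genes of each type are near-silent elsewhere and strongly expressed
    in their own type; program genes carry a moderate fold elevation, giving
    the whole-transcriptome correlation structure that drives clustering.
    Dropout is logistic in the gene's log2 mean expression; batch effects are
    per-gene log2 shifts.  TPM columns are renormalized after dropout.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_types = len(config.population_names)
    sizes = largest_remainder(config.n_cells, config.population_proportions)
    type_of_cell = np.repeat(np.arange(n_types), sizes)

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    cells = [f"cell{j:04d}" for j in range(config.n_cells)]

    # gene roles: a seeded permutation assigns marker and program blocks
    perm = rng.permutation(config.n_genes)
    marker_of = np.full(config.n_genes, "", dtype=object)
    program_of = np.full(config.n_genes, "", dtype=object)
    pos = 0
    marker_idx = {}
    for t, name in enumerate(config.population_names):
        idx = perm[pos : pos + config.n_markers_per_type]
        marker_of[idx] = name
        marker_idx[t] = idx
        pos += config.n_markers_per_type
    program_idx = {}
    for t, name in enumerate(config.population_names):
        idx = perm[pos : pos + config.n_program_genes_per_type]
        program_of[idx] = name
        program_idx[t] = idx
        pos += config.n_program_genes_per_type

    base_mean = rng.lognormal(mean=0.7, sigma=1.2, size=config.n_genes)
    type_mean = np.tile(base_mean[:, None], (1, n_types))
    for t in range(n_types):
        type_mean[marker_idx[t], :] = config.marker_baseline_mean
        type_mean[marker_idx[t], t] = config.marker_high_mean
        type_mean[program_idx[t], t] = base_mean[program_idx[t]] * config.program_fold

    batches = rng.integers(0, config.n_batches, size=config.n_cells)
    batch_shift = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes))

    mean_matrix = type_mean[:, type_of_cell]  # genes x cells
    mean_matrix = mean_matrix * np.power(2.0, batch_shift[batches, :].T)

    # library-size scaling (lognormal with the configured mean/sd)
    m, s = config.library_size_mean, config.library_size_sd
    mu = np.log(m**2 / np.sqrt(m**2 + s**2))
    sig = np.sqrt(np.log(1.0 + s**2 / m**2))
    lib = rng.lognormal(mean=mu, sigma=sig, size=config.n_cells)
    colsum = mean_matrix.sum(axis=0)
    mean_matrix = mean_matrix * (lib / colsum)[None, :]

    # negative-binomial counts via gamma-Poisson mixing
    d = config.nb_dispersion
    if d > 0:
        lam = rng.gamma(shape=1.0 / d, scale=mean_matrix * d)
    else:
        lam = mean_matrix
    counts = rng.poisson(lam).astype(np.int64)

    # logistic dropout vs log2 mean expression
    gene_mean = mean_matrix.mean(axis=1)
    if np.isneginf(config.dropout_midpoint):
        p_drop = np.zeros(config.n_genes)
    else:
        x = config.dropout_slope * (np.log2(1.0 + gene_mean) - config.dropout_midpoint)
        p_drop = 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))
    keep = rng.random(counts.shape) >= p_drop[:, None]
    counts = counts * keep

    eff_length = rng.uniform(500.0, 3000.0, size=config.n_genes)
    rate = counts / eff_length[:, None]
    rate_sum = rate.sum(axis=0)
    rate_sum[rate_sum == 0] = 1.0
    tpm = rate / rate_sum[None, :] * 1e6

    ssc_loc = np.asarray(config.ssc_location_per_type, dtype=float)
    ssc = rng.normal(ssc_loc[type_of_cell], config.ssc_sd)
    has_vdj = np.zeros(config.n_cells, dtype=bool)
    t_cells = type_of_cell == 0
    has_vdj[t_cells] = rng.random(int(t_cells.sum())) < config.vdj_fraction

    cell_meta = pd.DataFrame(
        {
            "batch": [f"batch{b + 1}" for b in batches],
            "true_type": [config.population_names[t] for t in type_of_cell],
            "ssc": ssc,
            "mapped_reads": counts.sum(axis=0),
            "has_vdj": has_vdj,
        },
        index=pd.Index(cells, name="cell"),
    )
    gene_meta = pd.DataFrame(
        {"marker_of": marker_of, "program_of": program_of, "eff_length": eff_length},
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionDataset(
        tpm=pd.DataFrame(tpm, index=gene_meta.index, columns=cell_meta.index),
        counts=pd.DataFrame(counts, index=gene_meta.index, columns=cell_meta.index),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
        config=config,
    )


# ---------------------------------------------------------------------------
# germline segments and reads


@dataclass
class SegmentSet:
    """Germline V and J nucleotide segments.

    ``v_segments``: list of (name, sequence, reading-frame offset);
    ``j_segments``: list of (name, sequence).
    """

    v_segments: list
    j_segments: list

    def v_names(self) -> list[str]:
        return [v[0] for v in self.v_segments]

    def j_names(self) -> list[str]:
        return [j[0] for j in self.j_segments]


def _has_stop(seq: str, frame: int) -> bool:
    for i in range(frame, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True
    return False


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def generate_germline_segments(
    n_v: int,
    n_j: int,
    len_v: int = 60,
    len_j: int = 30,
    seed: int = 0,
    max_identity: float = 0.9,
    max_retries: int = 200,
) -> SegmentSet:
    """Random germline segments with unambiguous pairwise identity (< 90%).

    V segments carry reading-frame offset 0 and contain no stop codon in that
    frame; J segments are generated stop-free in all three frames so that a
    productive recombinant exists for any junction length.  Generation fails
    explicitly if the identity constraint cannot be met within the retry
    budget.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need at least one V and one J segment")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []

    def draw(length: int, frames) -> str:
        for _ in range(max_retries):
            s = _random_seq(rng, length)
            if any(_has_stop(s, f) for f in frames):
                continue
            if all(pairwise_identity(s, other) < max_identity for other in accepted):
                accepted.append(s)
                return s
        raise RuntimeError(
            "could not generate a segment satisfying the stop-codon and "
            f"identity (<{max_identity:.0%}) constraints in {max_retries} tries"
        )

    v_segments = [(f"V{i + 1}", draw(len_v, (0,)), 0) for i in range(n_v)]
    j_segments = [(f"J{i + 1}", draw(len_j, (0, 1, 2))) for i in range(n_j)]
    return SegmentSet(v_segments=v_segments, j_segments=j_segments)


@dataclass
class ReadSet:
    """Per-cell read pairs with origin truth tags.

    ``pairs``: list of (read1, read2, origin) with origin in {background, vdj};
    ``truth``: dict with the planted recombinant (v, j, junction, sequence) or
    None for cells without a recombined transcript.
    """

    cell_id: str
    pairs: list
    truth: dict | None = None


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        arr[i] = BASES[(BASES.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def _productive_recombinant(
    rng: np.random.Generator,
    v_seq: str,
    v_frame: int,
    j_seq: str,
    junction_max: int,
) -> tuple[str, str]:
    """Build V + junction + J with no stop codon in the V reading frame.

    Junction length is uniform on 0..junction_max; bases are resampled until
    the recombinant is stop-free (a zero-length junction whose boundary codon
    stops triggers a length redraw).
    """
    jl = int(rng.integers(0, junction_max + 1))
    for _ in range(500):
        junction = _random_seq(rng, jl)
        rec = v_seq + junction + j_seq
        if not _has_stop(rec, v_frame):
            return rec, junction
        if jl == 0:
            jl = int(rng.integers(0, junction_max + 1))
    raise RuntimeError("could not build a productive recombinant")


def generate_cell_reads(
    dataset: ExpressionDataset,
    segments: SegmentSet,
    read_len: int = 50,
    n_background: int = 100,
    n_vdj: int = 50,
    error_rate: float = 0.01,
    seed: int = 0,
    junction_max: int = 10,
    n_decoys: int = 20,
    decoy_len: int = 500,
    leader_len: int = 20,
    constant_len: int = 50,
) -> list[ReadSet]:
    """Per-cell paired reads: background decoy reads plus, for cells with a
    recombined transcript, reads drawn uniformly from the full recombined
    transcript (leader + V + junction + J + constant) with per-base
    substitution errors."""
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    min_rec = min(len(v[1]) for v in segments.v_segments) + min(
        len(j[1]) for j in segments.j_segments
    )
    if read_len > min_rec:
        raise ValueError("read_len exceeds the shortest possible recombinant")
    rng = np.random.default_rng(seed)
    # the expressed transcript extends beyond the recombined V..J core: an
    # upstream leader and a downstream constant region (shared across cells),
    # so reads can tile the V and J termini
    leader = _random_seq(rng, leader_len)
    constant = _random_seq(rng, constant_len)
    decoys = [_random_seq(rng, decoy_len) for _ in range(n_decoys)]

    def sample_pairs(template: str, n: int, origin: str) -> list:
        out = []
        span = len(template) - read_len
        for _ in range(n):
            p1 = int(rng.integers(0, span + 1))
            p2 = int(rng.integers(0, span + 1))
            r1 = _mutate(rng, template[p1 : p1 + read_len], error_rate)
            r2 = _mutate(rng, revcomp(template[p2 : p2 + read_len]), error_rate)
            out.append((r1, r2, origin))
        return out

    readsets = []
    for cell_id, row in dataset.cell_meta.iterrows():
        pairs: list = []
        truth = None
        if bool(row["has_vdj"]):
            vi = int(rng.integers(0, len(segments.v_segments)))
            ji = int(rng.integers(0, len(segments.j_segments)))
            v_name, v_seq, v_frame = segments.v_segments[vi]
            j_name, j_seq = segments.j_segments[ji]
            rec, junction = _productive_recombinant(rng, v_seq, v_frame, j_seq, junction_max)
            transcript = leader + rec + constant
            truth = {
                "v": v_name,
                "j": j_name,
                "junction": junction,
                "sequence": rec,
                "transcript": transcript,
            }
            pairs.extend(sample_pairs(transcript, n_vdj, "vdj"))
        for _ in range(n_background):
            decoy = decoys[int(rng.integers(0, n_decoys))]
            pairs.extend(sample_pairs(decoy, 1, "background"))
        readsets.append(ReadSet(cell_id=str(cell_id), pairs=pairs, truth=truth))
    return readsets


# ---------------------------------------------------------------------------
# annotation and paralog tables


def generate_annotation_tables(
    n_genes_per_set: int,
    planted_ortholog_props: Mapping[str, Mapping[str, float]],
    identity_means: Mapping[str, float] | None = None,
    dnds_means: Mapping[str, float] | None = None,
    identity_sd: float = 8.0,
    dnds_sd: float = 0.08,
    localization: Mapping[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """BioMart-style per-gene annotation table with planted conservation.

    One row per gene: gene id, gene_set, localization class, per-species
    ortholog presence (Bernoulli with the planted proportion), per-species %
    identity (normal, truncated to [0, 100], only where an ortholog exists),
    and dN/dS (normal truncated at 0).  Set names ending in ``_TM`` default to
    the TM_or_secreted localization class, others to cytoplasmic_or_nuclear.
    """
    for set_name, per_species in planted_ortholog_props.items():
        for sp, p in per_species.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"ortholog proportion for {set_name}/{sp} not in [0,1]")
    rng = np.random.default_rng(seed)
    species = sorted({sp for m in planted_ortholog_props.values() for sp in m})
    rows = []
    for set_name in sorted(planted_ortholog_props):
        per_species = planted_ortholog_props[set_name]
        if localization and set_name in localization:
            loc = localization[set_name]
        else:
            loc = "TM_or_secreted" if set_name.endswith("_TM") else "cytoplasmic_or_nuclear"
        id_mean = (identity_means or {}).get(set_name, 70.0)
        dnds_mean = (dnds_means or {}).get(set_name, None)
        for i in range(n_genes_per_set):
            row = {
                "gene": f"{set_name}:{i:04d}",
                "gene_set": set_name,
                "localization": loc,
            }
            for sp in species:
                present = bool(rng.random() < per_species.get(sp, 0.0))
                row[f"ortholog_{sp}"] = present
                ident = float(np.clip(rng.normal(id_mean, identity_sd), 0.0, 100.0))
                row[f"identity_{sp}"] = ident if present else np.nan
            if dnds_mean is not None:
                row["dnds"] = float(max(rng.normal(dnds_mean, dnds_sd), 0.0))
            else:
                row["dnds"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


INFORMATIVE_PATTERNS = (
    "C1-specific",
    "C2-specific",
    "C3-specific",
    "C1-depleted",
    "C2-depleted",
    "C3-depleted",
)


@dataclass
class ParalogFamilies:
    """Planted paralog pairs with truth expression patterns."""

    pairs: pd.DataFrame  # gene_a, gene_b, taxon
    planted_patterns: dict = field(default_factory=dict)
    planted_diverged: list = field(default_factory=list)


def generate_paralog_families(
    n_recent_pairs: int = 37,
    n_early_pairs: int = 129,
    divergence_prob_recent: float = 0.62,
    divergence_prob_early: float = 0.94,
    seed: int = 0,
) -> ParalogFamilies:
    """Paralog pairs labelled with duplication-node taxa and planted patterns.

    Default pair counts and divergence probabilities reproduce the observed
    23/37 (recent) and 121/129 (early) diverged fractions.  Planted patterns
    are drawn from the informative (specific/depleted) labels so every pair is
    classifiable.
    """
    for p in (divergence_prob_recent, divergence_prob_early):
        if not 0.0 <= p <= 1.0:
            raise ValueError("divergence probabilities must be in [0,1]")
    rng = np.random.default_rng(seed)
    recent_taxa = sorted(RECENT_TAXA)
    early_taxa = sorted(EARLY_TAXA)
    rows, patterns, diverged_flags = [], {}, []
    k = 0
    for n_pairs, p_div, taxa in (
        (n_recent_pairs, divergence_prob_recent, recent_taxa),
        (n_early_pairs, divergence_prob_early, early_taxa),
    ):
        for _ in range(n_pairs):
            a, b = f"par{k:04d}a", f"par{k:04d}b"
            k += 1
            taxon = taxa[int(rng.integers(0, len(taxa)))]
            diverged = bool(rng.random() < p_div)
            la = INFORMATIVE_PATTERNS[int(rng.integers(0, len(INFORMATIVE_PATTERNS)))]
            if diverged:
                lb = la
                while lb == la:
                    lb = INFORMATIVE_PATTERNS[int(rng.integers(0, len(INFORMATIVE_PATTERNS)))]
            else:
                lb = la
            rows.append({"gene_a": a, "gene_b": b, "taxon": taxon})
            patterns[a] = la
            patterns[b] = lb
            diverged_flags.append(diverged)
    return ParalogFamilies(
        pairs=pd.DataFrame(rows),
        planted_patterns=patterns,
        planted_diverged=diverged_flags,
    )


# ---------------------------------------------------------------------------
# writers


def write_expression_dataset(dataset: ExpressionDataset, outdir) -> dict:
    """Write TPM/count TSVs, MTX triplets, metadata TSVs, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(dataset.tpm_matrix(), outdir / "tpm.tsv")
    write_matrix_tsv(dataset.counts_matrix(), outdir / "counts.tsv")
    write_matrix_mtx(dataset.tpm_matrix(), outdir / "tpm")
    dataset.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    dataset.gene_meta.to_csv(outdir / "gene_meta.tsv", sep="\t")
    manifest = {
        "config": asdict(dataset.config),
        "files": sorted(p.name for p in outdir.iterdir()),
        "n_genes": int(dataset.tpm.shape[0]),
        "n_cells": int(dataset.tpm.shape[1]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_segments_fasta(segments: SegmentSet, v_path, j_path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    v_recs = [
        SeqRecord(Seq(seq), id=name, description=f"frame={frame}")
        for name, seq, frame in segments.v_segments
    ]
    j_recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in segments.j_segments]
    SeqIO.write(v_recs, str(v_path), "fasta")
    SeqIO.write(j_recs, str(j_path), "fasta")


def read_segments_fasta(v_path, j_path) -> SegmentSet:
    from Bio import SeqIO

    v_segments = []
    for rec in SeqIO.parse(str(v_path), "fasta"):
        frame = 0
        for tok in rec.description.split():
            if tok.startswith("frame="):
                frame = int(tok.split("=", 1)[1])
        v_segments.append((rec.id, str(rec.seq).upper(), frame))
    j_segments = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(j_path), "fasta")]
    return SegmentSet(v_segments=v_segments, j_segments=j_segments)


def write_readsets_fastq(readsets: Sequence[ReadSet], outdir) -> None:
    """One gzip FASTQ pair per cell: <cell>_1.fastq.gz / <cell>_2.fastq.gz."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rs in readsets:
        for mate in (1, 2):
            path = outdir / f"{rs.cell_id}_{mate}.fastq.gz"
            with gzip.open(path, "wt") as fh:
                for i, pair in enumerate(rs.pairs):
                    seq = pair[mate - 1]
                    fh.write(f"@{rs.cell_id}:{i}/{mate} origin={pair[2]}\n")
                    fh.write(seq + "\n+\n" + "I" * len(seq) + "\n")
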