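"""Synthetic-data generator contracts: determinism, planted structure, formats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immevo import synthetic as syn
from immevo.align import revcomp


# ---------------------------------------------------------------------------
# population allocation


@pytest.mark.parametrize(
    "n, props, expected",
    [
        (300, (0.65, 0.31, 0.04), [195, 93, 12]),
        (10, (0.5, 0.5), [5, 5]),
        (7, (0.5, 0.25, 0.25), [3, 2, 2]),
        (3, (0.5, 0.5), [2, 1]),  # remainder tie -> earlier index wins
        (3, (0.9, 0.1, 0.0), [3, 0, 0]),
    ],
)
def test_largest_remainder(n, props, expected):
    assert list(syn.largest_remainder(n, props)) == expected


def test_largest_remainder_always_sums():
    rng = np.random.default_rng(0)
    for _ in range(200):
        k = rng.integers(2, 6)
        p = rng.dirichlet(np.ones(k))
        n = int(rng.integers(1, 500))
        alloc = syn.largest_remainder(n, p)
        assert alloc.sum() == n and (alloc >= 0).all()


# ---------------------------------------------------------------------------
# expression dataset


def test_expression_dataset_deterministic():
    cfg = syn.SyntheticConfig(n_cells=40, n_genes=300, n_markers_per_type=5,
                              n_program_genes_per_type=20, seed=1)
    a = syn.generate_expression_dataset(cfg)
    b = syn.generate_expression_dataset(cfg)
    pd.testing.assert_frame_equal(a.tpm, b.tpm)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.cell_meta, b.cell_meta)


def test_tpm_columns_normalized(small_dataset):
    colsums = small_dataset.tpm.sum(axis=0)
    assert np.abs(colsums - 1e6).max() < 1e-3


def test_dropout_limit_case_no_extra_zeros():
    # midpoint -inf disables dropout entirely: slope has no effect
    base = dict(n_cells=30, n_genes=200, n_markers_per_type=3,
                n_program_genes_per_type=10, seed=9,
                dropout_midpoint=-np.inf)
    a = syn.generate_expression_dataset(syn.SyntheticConfig(**base, dropout_slope=0.0))
    b = syn.generate_expression_dataset(syn.SyntheticConfig(**base, dropout_slope=5.0))
    pd.testing.assert_frame_equal(a.counts, b.counts)


def test_marker_genes_elevated_in_own_type_only(small_dataset):
    ds = small_dataset
    for name in ds.config.population_names:
        markers = ds.gene_meta.index[ds.gene_meta["marker_of"] == name]
        own = ds.cell_meta.index[ds.cell_meta["true_type"] == name]
        other = ds.cell_meta.index[ds.cell_meta["true_type"] != name]
        own_mean = ds.tpm.loc[markers, own].to_numpy().mean()
        other_mean = ds.tpm.loc[markers, other].to_numpy().mean()
        assert own_mean > 10 * other_mean


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        syn.SyntheticConfig(population_proportions=(0.5, 0.4, 0.05)).validate()
    with pytest.raises(ValueError, match="n_genes too small"):
        syn.SyntheticConfig(n_genes=10).validate()


def test_zero_proportion_population_allowed():
    cfg = syn.SyntheticConfig(n_cells=20, population_proportions=(0.6, 0.4, 0.0),
                              n_genes=300, n_markers_per_type=3,
                              n_program_genes_per_type=5, seed=2)
    ds = syn.generate_expression_dataset(cfg)
    vc = ds.cell_meta["true_type"].value_counts()
    assert vc.get("myeloid", 0) == 0 and vc.sum() == 20


# ---------------------------------------------------------------------------
# germline segments


def test_segment_counts_and_determinism():
    a = syn.generate_germline_segments(2, 3, len_v=60, len_j=30, seed=7)
    b = syn.generate_germline_segments(2, 3, len_v=60, len_j=30, seed=7)
    assert len(a.v_segments) == 2 and len(a.j_segments) == 3
    assert a.v_segments == b.v_segments and a.j_segments == b.j_segments
    assert all(len(s) == 60 for _, s, _ in a.v_segments)
    assert all(len(s) == 30 for _, s in a.j_segments)


def test_segments_pairwise_identity_below_threshold(toy_segments):
    """Independent check with Biopython's local aligner at the same scoring."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    seqs = [s for _, s, _ in toy_segments.v_segments] + [s for _, s in toy_segments.j_segments]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            aln = aligner.align(seqs[i], seqs[j])[0]
            matches = sum(
                1
                for a, b in zip(str(aln[0]), str(aln[1]))
                if a == b and a != "-"
            )
            assert matches / min(len(seqs[i]), len(seqs[j])) < 0.9


def test_v_segments_stop_free_in_frame(toy_segments):
    stops = {"TAA", "TAG", "TGA"}
    for _, seq, frame in toy_segments.v_segments:
        codons = {seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)}
        assert not (codons & stops)


# ---------------------------------------------------------------------------
# reads


def test_reads_error_free_are_substrings(toy_segments):
    cfg = syn.SyntheticConfig(n_cells=6, population_proportions=(1.0, 0.0, 0.0),
                              n_genes=100, n_markers_per_type=2,
                              n_program_genes_per_type=5, seed=3)
    ds = syn.generate_expression_dataset(cfg)
    readsets = syn.generate_cell_reads(ds, toy_segments, read_len=50, n_background=10,
                                       n_vdj=20, error_rate=0.0, seed=4)
    for rs in readsets:
        assert rs.truth is not None
        t = rs.truth["transcript"]
        assert rs.truth["sequence"] in t
        for r1, r2, origin in rs.pairs:
            if origin == "vdj":
                assert r1 in t and revcomp(r2) in t


def test_cells_without_recombinant_get_no_vdj_reads(toy_segments):
    cfg = syn.SyntheticConfig(n_cells=6, population_proportions=(0.0, 1.0, 0.0),
                              n_genes=100, n_markers_per_type=2,
                              n_program_genes_per_type=5, seed=3)
    ds = syn.generate_expression_dataset(cfg)
    readsets = syn.generate_cell_reads(ds, toy_segments, read_len=50, n_background=15,
                                       n_vdj=20, error_rate=0.0, seed=4)
    for rs in readsets:
        assert rs.truth is None
        assert all(origin == "background" for _, _, origin in rs.pairs)
        assert len(rs.pairs) == 15


def test_error_rate_validated(small_dataset, toy_segments):
    with pytest.raises(ValueError, match="error_rate"):
        syn.generate_cell_reads(small_dataset, toy_segments, error_rate=0.5)


def test_junction_length_distribution_uniform(toy_segments):
    cfg = syn.SyntheticConfig(n_cells=1000, population_proportions=(1.0, 0.0, 0.0),
                              n_genes=30, n_markers_per_type=1,
                              n_program_genes_per_type=2, seed=11)
    ds = syn.generate_expression_dataset(cfg)
    readsets = syn.generate_cell_reads(ds, toy_segments, read_len=50, n_background=0,
                                       n_vdj=1, error_rate=0.0, seed=12)
    lengths = [len(rs.truth["junction"]) for rs in readsets]
    counts = np.bincount(lengths, minlength=11)
    # uniform over 0..10 (small deficit at 0 possible from productivity redraws)
    chi2 = ((counts - len(lengths) / 11.0) ** 2 / (len(lengths) / 11.0)).sum()
    assert stats.chi2.sf(chi2, df=10) > 1e-3


# ---------------------------------------------------------------------------
# annotation and paralog tables


def test_annotation_planted_extremes_and_determinism():
    props = {"all_TM": {"mouse": 1.0, "fish": 0.0}}
    a = syn.generate_annotation_tables(50, props, seed=8)
    b = syn.generate_annotation_tables(50, props, seed=8)
    pd.testing.assert_frame_equal(a, b)
    assert a["ortholog_mouse"].all()
    assert not a["ortholog_fish"].any()
    # identity only where an ortholog exists
    assert a["identity_mouse"].notna().all()
    assert a["identity_fish"].isna().all()
    assert a.loc[a["ortholog_mouse"], "identity_mouse"].between(0, 100).all()


def test_annotation_localization_from_set_suffix():
    t = syn.generate_annotation_tables(5, {"x_TM": {"m": 0.5}, "y_CN": {"m": 0.5}}, seed=0)
    assert (t.loc[t["gene_set"] == "x_TM", "localization"] == "TM_or_secreted").all()
    assert (t.loc[t["gene_set"] == "y_CN", "localization"] == "cytoplasmic_or_nuclear").all()


def test_paralog_families_planted_structure():
    fams = syn.generate_paralog_families(
        n_recent_pairs=50, n_early_pairs=50,
        divergence_prob_recent=0.0, divergence_prob_early=1.0, seed=1,
    )
    from immevo.paralogs import RECENT_TAXA, EARLY_TAXA

    taxa = set(fams.pairs["taxon"])
    assert taxa <= (RECENT_TAXA | EARLY_TAXA)
    recent = fams.pairs.iloc[:50]
    assert set(recent["taxon"]) <= RECENT_TAXA
    # divergence prob 0 -> all recent pairs share the planted pattern
    for _, row in recent.iterrows():
        assert fams.planted_patterns[row["gene_a"]] == fams.planted_patterns[row["gene_b"]]
    early = fams.pairs.iloc[50:]
    for _, row in early.iterrows():
        assert fams.planted_patterns[row["gene_a"]] != fams.planted_patterns[row["gene_b"]]


def test_paralog_divergence_binomial_mean():
    fams = syn.generate_paralog_families(n_recent_pairs=37, n_early_pairs=0,
                                         divergence_prob_recent=0.62, seed=3)
    n_div = sum(fams.planted_diverged)
    # expected ~23 of 37; allow 3 binomial SDs
    sd = np.sqrt(37 * 0.62 * 0.38)
    assert abs(n_div - 37 * 0.62) <= 3 * sd


# ---------------------------------------------------------------------------
# writers


def test_dataset_roundtrip_via_tsv(tmp_path, small_dataset):
    manifest = syn.write_expression_dataset(small_dataset, tmp_path / "ds")
    assert "tpm.tsv" in manifest["files"]
    from immevo.matrix import read_matrix_tsv

    m = read_matrix_tsv(tmp_path / "ds" / "tpm.tsv", unit="TPM")
    assert m.values.shape == small_dataset.tpm.shape
    np.testing.assert_allclose(m.values.to_numpy(), small_dataset.tpm.to_numpy(), rtol=1e-9)


def test_fasta_and_fastq_writers(tmp_path, toy_segments):
    syn.write_segments_fasta(toy_segments, tmp_path / "v.fa", tmp_path / "j.fa")
    back = syn.read_segments_fasta(tmp_path / "v.fa", tmp_path / "j.fa")
    assert back.v_segments == toy_segments.v_segments
    assert back.j_segments == toy_segments.j_segments

    rs = syn.ReadSet(cell_id="cellX", pairs=[("ACGT" * 10, "TTTT" * 10, "background")])
    syn.write_readsets_fastq([rs], tmp_path)
    import gzip

    lines = gzip.open(tmp_path / "cellX_1.fastq.gz", "rt").read().splitlines()
    assert lines[1] == "ACGT" * 10 and lines[0].startswith("@cellX")
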