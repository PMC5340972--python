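"""V(D)J detection: reference construction, recruitment, assembly, annotation,
filtering, per-cell detection and association tests."""

import numpy as np
import pandas as pd
import pytest

from immevo import synthetic as syn, vdj
from immevo.align import revcomp, smith_waterman


# ---------------------------------------------------------------------------
# recombinant reference


def test_reference_cardinality_and_layout(toy_segments):
    ref = vdj.build_recombinant_reference(toy_segments)
    assert len(ref.entries) == 4 * 3
    v_len = len(toy_segments.v_segments[0][1])
    j_len = len(toy_segments.j_segments[0][1])
    for v_name, j_name, seq in ref.entries:
        assert len(seq) == 20 + v_len + 7 + j_len + 50
        assert seq.startswith("N" * 20) and seq.endswith("N" * 50)
        v_seq = dict((n, s) for n, s, _ in toy_segments.v_segments)[v_name]
        j_seq = dict(toy_segments.j_segments)[j_name]
        assert seq[20 : 20 + v_len] == v_seq
        assert seq[20 + v_len : 20 + v_len + 7] == "N" * 7
        assert seq[27 + v_len : 27 + v_len + j_len] == j_seq
    # V-major ordering is deterministic
    assert [e[0] for e in ref.entries[:3]] == ["V1", "V1", "V1"]


def test_reference_is_bijection(toy_segments):
    ref = vdj.build_recombinant_reference(toy_segments)
    pairs = {(v, j) for v, j, _ in ref.entries}
    assert len(pairs) == len(ref.entries)
    assert ref.decode(5) == (ref.entries[5][0], ref.entries[5][1])


def test_reference_rejects_empty():
    with pytest.raises(ValueError):
        vdj.build_recombinant_reference(syn.SegmentSet(v_segments=[], j_segments=[("J1", "ACGT")]))


# ---------------------------------------------------------------------------
# recruitment


def test_recruitment_exact_and_random_reads(toy_segments):
    v_seq = toy_segments.v_segments[0][1]
    exact = v_seq[:50]
    rng = np.random.default_rng(0)
    random_read = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
    rs = syn.ReadSet(
        cell_id="c",
        pairs=[(exact, revcomp(exact), "vdj"), (random_read, random_read, "background")],
    )
    recruited = vdj.recruit_reads(rs, toy_segments, k=25)
    assert exact in recruited and random_read not in recruited


def test_recruitment_matches_alignment_screen(toy_segments):
    """Recruitment set equals a full Smith-Waterman screen at the same threshold
    for error-free reads (k-mer hit <=> local alignment score >= k)."""
    rng = np.random.default_rng(1)
    k = 25
    pairs = []
    for i in range(50):  # true reads: windows of V/J germline
        seg = toy_segments.v_segments[i % 4][1]
        start = int(rng.integers(0, len(seg) - 40 + 1))
        r = seg[start : start + 40]
        pairs.append((r, revcomp(r), "vdj"))
    for _ in range(50):  # decoy reads
        r = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        pairs.append((r, revcomp(r), "background"))
    rs = syn.ReadSet(cell_id="c", pairs=pairs)
    recruited = set(vdj.recruit_reads(rs, toy_segments, k=k))
    all_seqs = [s for _, s, _f in toy_segments.v_segments] + [
        s for _, s in toy_segments.j_segments
    ]
    for r1, r2, _ in pairs:
        best = max(
            smith_waterman(mate, target).score
            for mate in (r1, r2, revcomp(r1), revcomp(r2))
            for target in all_seqs
        )
        assert (r1 in recruited) == (best >= k)


def test_recruitment_k_validation(toy_segments):
    rs = syn.ReadSet(cell_id="c", pairs=[("ACGTACGT", "ACGTACGT", "background")])
    with pytest.raises(ValueError, match="read length"):
        vdj.recruit_reads(rs, toy_segments, k=25)


# ---------------------------------------------------------------------------
# assembly


def test_assembly_merges_overlapping_reads():
    rng = np.random.default_rng(2)
    template = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
    a, b = template[:50], template[10:60]  # 40-base exact overlap
    contigs = vdj.assemble_contigs([a, b], min_overlap=31, min_reads=2)
    assert len(contigs) == 1
    assert contigs[0] in (template[:60], revcomp(template[:60]))


def test_assembly_tiling_reads_reconstruct_template():
    rng = np.random.default_rng(3)
    template = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    reads = [template[s : s + 50] for s in range(0, 251, 10)]
    contigs = vdj.assemble_contigs(reads, min_overlap=31, min_reads=2)
    assert len(contigs) == 1
    assert contigs[0] in (template, revcomp(template))


def test_assembly_unrelated_reads_never_merge():
    rng = np.random.default_rng(4)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    b = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    assert vdj.assemble_contigs([a, b], min_reads=2) == []
    both = vdj.assemble_contigs([a, b], min_reads=1)
    assert len(both) == 2


def test_assembly_handles_reverse_complement_reads():
    rng = np.random.default_rng(5)
    template = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
    reads = [template[:50], revcomp(template[15:65])]  # 35-base overlap
    contigs = vdj.assemble_contigs(reads, min_reads=2)
    assert len(contigs) == 1
    assert contigs[0] in (template[:65], revcomp(template[:65]))


# ---------------------------------------------------------------------------
# annotation


def test_annotate_constructed_contig(toy_segments):
    v_name, v_seq, _ = toy_segments.v_segments[1]
    j_name, j_seq = toy_segments.j_segments[2]
    junction = "ACGTC"
    contig = v_seq + junction + j_seq
    v_hit, j_hit, jn, ambiguous = vdj.annotate_contig(contig, toy_segments)
    assert v_hit.name == v_name and j_hit.name == j_name
    assert v_hit.identity == pytest.approx(100.0)
    assert v_hit.recovered == pytest.approx(1.0)
    assert j_hit.identity == pytest.approx(100.0)
    assert jn == junction
    assert not ambiguous
    # reverse complement: same hits, flagged strand
    v_rc, j_rc, jn_rc, _ = vdj.annotate_contig(revcomp(contig), toy_segments)
    assert (v_rc.name, j_rc.name, jn_rc) == (v_name, j_name, junction)
    assert v_rc.strand == "-"


def test_smith_waterman_matches_biopython_oracle():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    rng = np.random.default_rng(6)
    for _ in range(20):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        expected = aligner.align(a, b).score
        assert smith_waterman(a, b).score == pytest.approx(max(expected, 0.0))


# ---------------------------------------------------------------------------
# filtering


def _hit(name="V1", identity=99.0, recovered=0.95, qcov=0.95, frame=0,
         q_start=0, q_end=60, s_start=0, s_end=60):
    return vdj.SegmentHit(
        name=name, identity=identity, recovered=recovered, contig_coverage=qcov,
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        strand="+", score=50.0, frame=frame,
    )


def test_call_passes_with_good_hits(toy_segments):
    v_name, v_seq, _ = toy_segments.v_segments[0]
    j_name, j_seq = toy_segments.j_segments[0]
    contig = v_seq + j_seq
    v = _hit(v_name, identity=95.0, recovered=0.95, q_end=len(v_seq), s_end=len(v_seq))
    j = _hit(j_name, identity=99.0, recovered=0.98,
             q_start=len(v_seq), q_end=len(contig), s_end=len(j_seq))
    call = vdj.call_recombination(v, j, contig)
    assert call.passed and call.reasons == []


def test_call_fails_on_stop_codon():
    v_seq = "ATGGCA" * 10
    j_seq = "GGCGCA" * 5
    junction = "TAA"  # in-frame stop in the junction
    contig = v_seq + junction + j_seq
    v = _hit(identity=100.0, recovered=1.0, qcov=1.0, q_end=60, s_end=60)
    j = _hit("J1", identity=100.0, recovered=1.0, qcov=1.0,
             q_start=63, q_end=93, s_end=30)
    call = vdj.call_recombination(v, j, contig, junction=junction)
    assert not call.passed and "stop codon" in call.reasons


def test_call_fails_below_identity_threshold():
    call = vdj.call_recombination(
        _hit(identity=85.0), _hit("J1", q_start=65, q_end=95), "A" * 100
    )
    assert not call.passed
    assert any("V identity < 90" in r for r in call.reasons)


def test_call_missing_hits_enumerated():
    call = vdj.call_recombination(None, None, "ACGT")
    assert call.reasons == ["no V hit", "no J hit"]


def test_call_identity_monotonicity(toy_segments):
    """Lowering min_identity never turns a passing call into a failing one."""
    v_name, v_seq, _ = toy_segments.v_segments[0]
    j_name, j_seq = toy_segments.j_segments[0]
    contig = v_seq + j_seq
    for ident in (99.0, 95.0, 91.0):
        v = _hit(v_name, identity=ident, recovered=0.95, q_end=len(v_seq), s_end=len(v_seq))
        j = _hit(j_name, identity=ident, recovered=0.95,
                 q_start=len(v_seq), q_end=len(contig), s_end=len(j_seq))
        strict = vdj.call_recombination(v, j, contig, min_identity=90.0)
        loose = vdj.call_recombination(v, j, contig, min_identity=80.0)
        assert (not strict.passed) or loose.passed


# ---------------------------------------------------------------------------
# per-cell detection


def _readsets(toy_segments, n_pos, n_neg, seed, error_rate=0.0, n_vdj=20, n_background=50):
    total = n_pos + n_neg
    cfg = syn.SyntheticConfig(
        n_cells=total,
        population_proportions=(n_pos / total, 1 - n_pos / total, 0.0),
        n_genes=100, n_markers_per_type=2, n_program_genes_per_type=5, seed=seed,
    )
    ds = syn.generate_expression_dataset(cfg)
    readsets = syn.generate_cell_reads(
        ds, toy_segments, read_len=50, n_background=n_background, n_vdj=n_vdj,
        error_rate=error_rate, seed=seed + 1,
    )
    return ds, readsets


def test_detect_error_free_is_perfect(toy_segments):
    ds, readsets = _readsets(toy_segments, n_pos=5, n_neg=5, seed=21)
    calls = vdj.detect_cell_vdj(readsets, toy_segments)
    for rs in readsets:
        positive = any(c.passed for c in calls[rs.cell_id])
        if rs.truth is None:
            assert not positive
        else:
            assert positive
            best = [c for c in calls[rs.cell_id] if c.passed][0]
            assert (best.v_hit.name, best.j_hit.name) == (rs.truth["v"], rs.truth["j"])


def test_detect_strand_symmetry(toy_segments):
    ds, readsets = _readsets(toy_segments, n_pos=3, n_neg=2, seed=23)
    flipped = [
        syn.ReadSet(
            cell_id=rs.cell_id,
            pairs=[(revcomp(r1), revcomp(r2), o) for r1, r2, o in rs.pairs],
            truth=rs.truth,
        )
        for rs in readsets
    ]
    a = vdj.detect_cell_vdj(readsets, toy_segments)
    b = vdj.detect_cell_vdj(flipped, toy_segments)
    for rs in readsets:
        assert any(c.passed for c in a[rs.cell_id]) == any(c.passed for c in b[rs.cell_id])


def test_calls_to_table_structure(toy_segments):
    ds, readsets = _readsets(toy_segments, n_pos=1, n_neg=1, seed=29)
    table = vdj.calls_to_table(vdj.detect_cell_vdj(readsets, toy_segments))
    assert {"cell", "passed", "v", "j", "reasons"} <= set(table.columns)
    assert table["passed"].any()


# ---------------------------------------------------------------------------
# association


def test_associate_perfect_association_matches_enumeration():
    import math

    pos = pd.Series([True] * 20 + [False] * 20)
    clusters = pd.Series([1] * 20 + [2] * 20)
    trbc = pd.Series([10.0] * 20 + [0.0] * 20)
    res = vdj.associate_vdj(pos, clusters, trbc)
    expected = 2.0 / math.comb(40, 20)
    assert res["p_cluster"] == pytest.approx(expected, rel=1e-9)
    assert res["p_trbc1"] == pytest.approx(expected, rel=1e-9)


def test_associate_degenerate_flagged():
    pos = pd.Series([False] * 10)
    res = vdj.associate_vdj(pos, pd.Series([1] * 5 + [2] * 5), pd.Series([1.0] * 10))
    assert res["p_cluster"] == 1.0 and res["flag_cluster"] == "degenerate margin"


def test_associate_null_p_uniformish():
    rng = np.random.default_rng(31)
    ps = []
    for _ in range(200):
        pos = pd.Series(rng.random(40) < 0.5)
        clusters = pd.Series(rng.integers(1, 3, 40))
        trbc = pd.Series(rng.random(40) * 10)
        ps.append(vdj.associate_vdj(pos, clusters, trbc)["p_cluster"])
    # Fisher p under the null is stochastically >= uniform (discrete test);
    # it must not be anti-conservative
    ps = np.array(ps)
    for alpha in (0.05, 0.1, 0.25):
        assert (ps <= alpha).mean() <= alpha + 0.05
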