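"""Per-cell TCR-beta V(D)J recombination detection from short reads.

The detector follows the synthetic-recombinant-reference strategy: all V x J
combinations are concatenated with N padding (20 N upstream for the unknown
leader, 7 N between V and J for a possible D segment, 50 N downstream for the
constant region).  Reads are recruited by exact k-mer sharing with the
germline segments (N positions carry no information), assembled with a greedy
suffix-prefix overlap-layout-consensus step, and contigs are annotated by
Smith-Waterman local alignment against every germline segment.  A contig is
evidence for recombination when both a V and a J hit reach >= 90% identity,
>= 90% germline recovery and >= 90% contig-side coverage, and the reading
frame set by the V segment contains no stop codon from V through J.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import fisher_exact_test
from .align import LocalAlignment, kmers, revcomp, smith_waterman
from .synthetic import ReadSet, SegmentSet, STOP_CODONS

__all__ = [
    "RecombinantReference",
    "SegmentHit",
    "RecombinationCall",
    "build_recombinant_reference",
    "recruit_reads",
    "assemble_contigs",
    "annotate_contig",
    "call_recombination",
    "detect_cell_vdj",
    "associate_vdj",
    "calls_to_table",
]


# ---------------------------------------------------------------------------
# reference


@dataclass
class RecombinantReference:
    """All V x J synthetic recombinants with N pads (5', junction, 3')."""

    entries: list  # (v_name, j_name, sequence)
    pads: tuple = (20, 7, 50)

    def decode(self, index: int) -> tuple[str, str]:
        v, j, _ = self.entries[index]
        return v, j


def build_recombinant_reference(
    segments: SegmentSet, pads: tuple = (20, 7, 50)
) -> RecombinantReference:
    """V-major ordered list of 20N + V + 7N + J + 50N synthetic sequences."""
    if not segments.v_segments or not segments.j_segments:
        raise ValueError("need at least one V and one J segment")
    p5, pj, p3 = pads
    entries = []
    for v_name, v_seq, _ in segments.v_segments:
        for j_name, j_seq in segments.j_segments:
            entries.append((v_name, j_name, "N" * p5 + v_seq + "N" * pj + j_seq + "N" * p3))
    return RecombinantReference(entries=entries, pads=tuple(pads))


# ---------------------------------------------------------------------------
# recruitment and assembly


def recruit_reads(readset: ReadSet, segments: SegmentSet, k: int = 25) -> list[str]:
    """Reads whose pair shares an exact k-mer (either strand) with any segment.

    Returns the flat list of mate sequences from recruited pairs.
    """
    if readset.pairs and k > min(len(p[0]) for p in readset.pairs):
        raise ValueError("k exceeds the read length")
    ref_kmers: set[str] = set()
    for _, seq, _f in segments.v_segments:
        ref_kmers |= kmers(seq, k)
        ref_kmers |= kmers(revcomp(seq), k)
    for _, seq in segments.j_segments:
        ref_kmers |= kmers(seq, k)
        ref_kmers |= kmers(revcomp(seq), k)
    recruited = []
    for r1, r2, _origin in readset.pairs:
        hit = any(
            any(read[i : i + k] in ref_kmers for i in range(len(read) - k + 1))
            for read in (r1, r2)
        )
        if hit:
            recruited.extend([r1, r2])
    return recruited


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap >= min_overlap, else 0."""
    for l in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a.endswith(b[:l]):
            return l
    return 0


def _excise_weak_kmers(
    reads: Sequence[str],
    k: int = 15,
    min_count: int = 2,
    min_piece: int = 32,
    min_median_coverage: int = 10,
) -> list[str]:
    """Split reads at singleton k-mers (spectrum-based error excision).

    Sequencing errors create k-mers seen only once in a deeply covered read
    pool; the affected window is excised and the flanking solid pieces are
    kept when long enough to still seed an overlap.  The filter only engages
    when the median canonical k-mer count reaches ``min_median_coverage``, so
    shallow desk-scale read sets pass through untouched.
    """
    counts: dict[str, int] = {}
    for r in reads:
        r = r.upper()
        for i in range(len(r) - k + 1):
            km = r[i : i + k]
            key = min(km, revcomp(km))
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return list(reads)
    # coverage gauge: median count over read windows (instance-weighted, so
    # singleton error k-mers cannot mask deep coverage of the true sequence)
    window_counts = [c for key, c in counts.items() for _ in range(c)]
    med = float(np.median(window_counts))
    if med < min_median_coverage:
        return list(reads)
    out = []
    for r in reads:
        r = r.upper()
        if len(r) < k:
            continue
        solid = [
            counts[min(r[i : i + k], revcomp(r[i : i + k]))] >= min_count
            for i in range(len(r) - k + 1)
        ]
        i = 0
        while i < len(solid):
            if solid[i]:
                j = i
                while j < len(solid) and solid[j]:
                    j += 1
                piece = r[i : j - 1 + k]
                if len(piece) >= min_piece:
                    out.append(piece)
                i = j
            else:
                i += 1
    return out


def assemble_contigs(
    reads: Sequence[str],
    min_overlap: int = 31,
    min_reads: int = 2,
    error_excision: bool = True,
) -> list[str]:
    """Greedy suffix-prefix overlap assembly.

    Repeatedly merges the pair of sequences with the longest exact overlap
    (both orientations considered; ties broken by the lexicographically
    smallest merged string) until no overlap of at least ``min_overlap``
    remains.  Contigs supported by fewer than ``min_reads`` reads are
    discarded; contained duplicates count as support.  At deep coverage an
    initial k-mer spectrum pass excises likely sequencing errors (see
    :func:`_excise_weak_kmers`), since exact-overlap merging is otherwise
    poisoned by erroneous read ends.
    """
    if error_excision:
        reads = _excise_weak_kmers(reads)
    # deduplicate, counting support; canonicalize orientation per unique string
    support: dict[str, int] = {}
    for r in reads:
        r = r.upper()
        rc = revcomp(r)
        key = min(r, rc)
        support[key] = support.get(key, 0) + 1
    items: list[tuple[str, int]] = sorted(support.items())
    # absorb contained sequences
    changed = True
    while changed:
        changed = False
        for i, (si, ci) in enumerate(items):
            for j, (sj, cj) in enumerate(items):
                if i == j:
                    continue
                if si in sj or revcomp(si) in sj:
                    items[j] = (sj, cj + ci)
                    del items[i]
                    changed = True
                    break
            if changed:
                break

    def candidates(seqs: list[tuple[str, int]]):
        # all relative orientations: left sequence forward or flipped, right
        # sequence forward or flipped ((R,R) is the global reverse complement
        # of (F,F) with the pair order swapped, hence redundant)
        best = (0, "", -1, -1)
        n = len(seqs)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                for fa, fb in ((False, False), (False, True), (True, False)):
                    a = revcomp(seqs[i][0]) if fa else seqs[i][0]
                    b = revcomp(seqs[j][0]) if fb else seqs[j][0]
                    l = _best_overlap(a, b, min_overlap)
                    if l:
                        merged = a + b[l:]
                        merged = min(merged, revcomp(merged))
                        cand = (l, merged, i, j)
                        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                            best = cand
        return best

    while len(items) > 1:
        l, merged, i, j = candidates(items)
        if l == 0:
            break
        ci, cj = items[i][1], items[j][1]
        items = [it for idx, it in enumerate(items) if idx not in (i, j)]
        items.append((merged, ci + cj))
        items.sort()
    return sorted(s for s, c in items if c >= min_reads)


# ---------------------------------------------------------------------------
# annotation and calling


@dataclass
class SegmentHit:
    """Best local alignment of a contig against one germline segment."""

    name: str
    identity: float  # percent over aligned columns
    recovered: float  # aligned germline span / germline length
    contig_coverage: float  # aligned contig span / eligible contig span
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+' or '-'
    score: float
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.recovered <= 1.0 and 0.0 <= self.identity <= 100.0):
            raise ValueError("segment hit fractions out of range")


@dataclass
class RecombinationCall:
    cell_id: str
    contig: str
    v_hit: SegmentHit | None
    j_hit: SegmentHit | None
    junction: str
    has_stop: bool
    passed: bool
    reasons: list = field(default_factory=list)
    ambiguous: bool = False


def _hit_from_alignment(
    name: str, aln: LocalAlignment, germline_len: int, strand: str, frame: int | None
) -> SegmentHit:
    span = aln.q_end - aln.q_start
    return SegmentHit(
        name=name,
        identity=aln.identity,
        recovered=(aln.s_end - aln.s_start) / germline_len,
        contig_coverage=min(1.0, span / germline_len) if germline_len else 0.0,
        q_start=aln.q_start,
        q_end=aln.q_end,
        s_start=aln.s_start,
        s_end=aln.s_end,
        strand=strand,
        score=aln.score,
        frame=frame,
    )


def annotate_contig(
    contig: str,
    segments: SegmentSet,
    min_score: float = 20.0,
    ambiguity_margin: float = 0.05,
) -> tuple[SegmentHit | None, SegmentHit | None, str, bool]:
    """Best V and J hits by Smith-Waterman on both strands, plus the junction.

    The contig strand is fixed by the best V hit; the best J hit is then taken
    on that strand.  Returns (v_hit, j_hit, junction, ambiguous) where
    ``ambiguous`` is True when a second (V, J) pairing scores within
    ``ambiguity_margin`` of the best combined score.
    """
    strands = {"+": contig.upper(), "-": revcomp(contig.upper())}
    v_hits: list[SegmentHit] = []
    for v_name, v_seq, v_frame in segments.v_segments:
        for strand, seq in strands.items():
            aln = smith_waterman(seq, v_seq)
            if aln.score >= min_score:
                v_hits.append(_hit_from_alignment(v_name, aln, len(v_seq), strand, v_frame))
    if not v_hits:
        return None, None, "", False
    v_hits.sort(key=lambda h: (-h.score, h.name))
    best_v = v_hits[0]
    oriented = strands[best_v.strand]
    j_hits: list[SegmentHit] = []
    for j_name, j_seq in segments.j_segments:
        aln = smith_waterman(oriented, j_seq)
        if aln.score >= min_score:
            j_hits.append(_hit_from_alignment(j_name, aln, len(j_seq), best_v.strand, None))
    if not j_hits:
        return best_v, None, "", False
    j_hits.sort(key=lambda h: (-h.score, h.name))
    best_j = j_hits[0]
    junction = (
        oriented[best_v.q_end : best_j.q_start] if best_j.q_start >= best_v.q_end else ""
    )
    # ambiguity: another (V, J) naming within the relative margin of the top
    ambiguous = False
    top = best_v.score + best_j.score
    second_v = next((h.score for h in v_hits if h.name != best_v.name), 0.0)
    second_j = next((h.score for h in j_hits if h.name != best_j.name), 0.0)
    runner = max(second_v + best_j.score, best_v.score + second_j)
    if runner >= (1.0 - ambiguity_margin) * top and runner > 0:
        if second_v >= (1.0 - ambiguity_margin) * best_v.score or second_j >= (
            1.0 - ambiguity_margin
        ) * best_j.score:
            ambiguous = True
    return best_v, best_j, junction, ambiguous


def _stop_in_v_frame(contig: str, v_hit: SegmentHit, j_hit: SegmentHit) -> bool:
    """Stop-codon scan from V through J in the frame set by the V segment.

    The frame is propagated from the V segment's annotated offset through the
    alignment start; junction-induced frameshifts therefore surface as
    downstream stop codons.
    """
    frame_offset = v_hit.frame or 0
    start = v_hit.q_start + ((frame_offset - v_hit.s_start) % 3)
    end = j_hit.q_end
    for i in range(start, end - 2, 3):
        if contig[i : i + 3] in STOP_CODONS:
            return True
    return False


def call_recombination(
    v_hit: SegmentHit | None,
    j_hit: SegmentHit | None,
    contig: str,
    cell_id: str = "",
    junction: str = "",
    ambiguous: bool = False,
    min_identity: float = 90.0,
    min_recovery: float = 0.9,
    min_qcov: float = 0.9,
    max_junction: int = 30,
) -> RecombinationCall:
    """Apply the evidence filters and record every violated criterion."""
    reasons = []
    if v_hit is None:
        reasons.append("no V hit")
    if j_hit is None:
        reasons.append("no J hit")
    has_stop = False
    oriented = contig
    if v_hit is not None and j_hit is not None:
        if v_hit.strand == "-":
            oriented = revcomp(contig.upper())
        else:
            oriented = contig.upper()
        for side, hit in (("V", v_hit), ("J", j_hit)):
            if hit.identity < min_identity:
                reasons.append(f"{side} identity < {min_identity:g}")
            if hit.recovered < min_recovery:
                reasons.append(f"{side} recovery < {min_recovery:g}")
            if hit.contig_coverage < min_qcov:
                reasons.append(f"{side} contig coverage < {min_qcov:g}")
        if len(junction) > max_junction:
            reasons.append(f"junction longer than {max_junction}")
        has_stop = _stop_in_v_frame(oriented, v_hit, j_hit)
        if has_stop:
            reasons.append("stop codon")
        if ambiguous:
            reasons.append("ambiguous segment assignment")
    return RecombinationCall(
        cell_id=cell_id,
        contig=contig,
        v_hit=v_hit,
        j_hit=j_hit,
        junction=junction,
        has_stop=has_stop,
        passed=not reasons,
        reasons=reasons,
        ambiguous=ambiguous,
    )


def detect_cell_vdj(
    readsets: Iterable[ReadSet],
    segments: SegmentSet,
    k: int = 25,
    min_overlap: int = 31,
    min_reads: int = 2,
    min_identity: float = 90.0,
    min_recovery: float = 0.9,
    min_qcov: float = 0.9,
) -> dict:
    """Recruit -> assemble -> annotate -> call, per cell.

    Returns a dict cell_id -> list of RecombinationCall (one per contig with a
    V or J hit).  A cell is V(D)J-positive when at least one call passes.
    """
    out: dict[str, list[RecombinationCall]] = {}
    for rs in readsets:
        calls: list[RecombinationCall] = []
        recruited = recruit_reads(rs, segments, k=k)
        contigs = assemble_contigs(recruited, min_overlap=min_overlap, min_reads=min_reads)
        for contig in contigs:
            v_hit, j_hit, junction, ambiguous = annotate_contig(contig, segments)
            if v_hit is None and j_hit is None:
                continue
            calls.append(
                call_recombination(
                    v_hit,
                    j_hit,
                    contig,
                    cell_id=rs.cell_id,
                    junction=junction,
                    ambiguous=ambiguous,
                    min_identity=min_identity,
                    min_recovery=min_recovery,
                    min_qcov=min_qcov,
                )
            )
        out[rs.cell_id] = calls
    return out


def calls_to_table(calls_by_cell: dict) -> pd.DataFrame:
    """Flatten per-cell calls into a TSV-ready table."""
    rows = []
    for cell_id, calls in calls_by_cell.items():
        if not calls:
            rows.append({"cell": cell_id, "passed": False, "v": "", "j": "", "reasons": "no contig"})
            continue
        for c in calls:
            rows.append(
                {
                    "cell": cell_id,
                    "passed": c.passed,
                    "v": c.v_hit.name if c.v_hit else "",
                    "j": c.j_hit.name if c.j_hit else "",
                    "v_identity": c.v_hit.identity if c.v_hit else np.nan,
                    "j_identity": c.j_hit.identity if c.j_hit else np.nan,
                    "v_recovery": c.v_hit.recovered if c.v_hit else np.nan,
                    "j_recovery": c.j_hit.recovered if c.j_hit else np.nan,
                    "junction": c.junction,
                    "reasons": "; ".join(c.reasons),
                }
            )
    return pd.DataFrame(rows)


def associate_vdj(
    vdj_positive: pd.Series,
    cluster_labels: pd.Series,
    trbc1_tpm: pd.Series,
    cluster_of_interest=1,
    tpm_threshold: float = 5.0,
) -> dict:
    """Fisher exact association of V(D)J positivity with cluster membership
    and with trbc1 expression (> tpm_threshold).

    Degenerate margins give p = 1 with a flag.
    """
    cells = vdj_positive.index
    pos = vdj_positive.astype(bool)
    in_c = cluster_labels.loc[cells] == cluster_of_interest
    hi_trbc = trbc1_tpm.loc[cells] > tpm_threshold

    def table(cond):
        return [
            [int((pos & cond).sum()), int((pos & ~cond).sum())],
            [int((~pos & cond).sum()), int((~pos & ~cond).sum())],
        ]

    res_c = fisher_exact_test(table(in_c))
    res_t = fisher_exact_test(table(hi_trbc))
    return {
        "p_cluster": res_c.pvalue,
        "p_trbc1": res_t.pvalue,
        "odds_cluster": res_c.statistic,
        "odds_trbc1": res_t.statistic,
        "flag_cluster": res_c.flag,
        "flag_trbc1": res_t.flag,
    }
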