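"""Nucleotide sequence utilities: reverse complement, k-mers, and local alignment.

The local aligner is a plain affine-gap Smith-Waterman (match +1, mismatch -2,
gap open -4, gap extend -1 by default), adequate for desk-scale annotation of
assembled contigs against short germline segments.  ``N`` matches any base at
zero score contribution, mirroring zero-N-penalty alignment settings used for
synthetic recombinant references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["revcomp", "kmers", "LocalAlignment", "smith_waterman", "pairwise_identity"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass
class LocalAlignment:
    """Result of a Smith-Waterman local alignment of query vs subject.

    Coordinates are 0-based half-open on the original (forward) sequences.
    ``matches``/``aligned_cols`` give percent identity over aligned columns.
    """

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    aligned_cols: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_cols if self.aligned_cols else 0.0


def smith_waterman(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> LocalAlignment:
    """Affine-gap Smith-Waterman local alignment with traceback.

    Returns the single best-scoring local alignment (ties broken toward the
    smallest end coordinates, then diagonal moves preferred in traceback,
    giving a deterministic result).
    """
    n, m = len(query), len(subject)
    if n == 0 or m == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in subject (consume query)
    F = np.full((n + 1, m + 1), NEG)  # gap in query (consume subject)
    q = query.upper()
    s = subject.upper()
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        Hi1 = H[i - 1]
        Hi = H[i]
        Ei = E[i]
        Ei1 = E[i - 1]
        Fi = F[i]
        for j in range(1, m + 1):
            sj = s[j - 1]
            if qi == "N" or sj == "N":
                sub = 0.0
            elif qi == sj:
                sub = match
            else:
                sub = mismatch
            e = max(Hi1[j] + gap_open, Ei1[j] + gap_extend)
            f = max(Hi[j - 1] + gap_open, Fi[j - 1] + gap_extend)
            h = Hi1[j - 1] + sub
            hmax = h
            if e > hmax:
                hmax = e
            if f > hmax:
                hmax = f
            if hmax < 0:
                hmax = 0.0
            Ei[j] = e
            Fi[j] = f
            Hi[j] = hmax
            if hmax > best:
                best, bi, bj = hmax, i, j
    if best <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)
    # traceback from (bi, bj)
    i, j = bi, bj
    matches = 0
    cols = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            a, b = q[i - 1], s[j - 1]
            if a == "N" or b == "N":
                sub = 0.0
            elif a == b:
                sub = match
            else:
                sub = mismatch
            if abs(H[i][j] - (H[i - 1][j - 1] + sub)) < 1e-9:
                cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] != "N":
                    matches += 1
                i -= 1
                j -= 1
            elif abs(H[i][j] - E[i][j]) < 1e-9:
                state = "E"
            elif abs(H[i][j] - F[i][j]) < 1e-9:
                state = "F"
            else:  # numerical guard: treat as diagonal
                cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] != "N":
                    matches += 1
                i -= 1
                j -= 1
        elif state == "E":
            cols += 1
            if abs(E[i][j] - (H[i - 1][j] + gap_open)) < 1e-9:
                state = "H"
            i -= 1
        else:  # F
            cols += 1
            if abs(F[i][j] - (H[i][j - 1] + gap_open)) < 1e-9:
                state = "H"
            j -= 1
    return LocalAlignment(
        score=float(best),
        q_start=i,
        q_end=bi,
        s_start=j,
        s_end=bj,
        matches=matches,
        aligned_cols=cols,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in the best local alignment.

    A conservative distinguishability measure for germline segments: two
    segments are considered ambiguous when most of the shorter one aligns
    exactly to the other.
    """
    aln = smith_waterman(a, b)
    return aln.matches / min(len(a), len(b)) if min(len(a), len(b)) else 0.0
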