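"""Seeded gapped local alignment for probe specificity checks.

A deliberately small BLASTN-like aligner: exact 11-mer seeding followed by
affine-gap Smith-Waterman (match +2, mismatch -3, gap of length k costs
5 + 2k) over a window around the seeds, on both strands.  It exists so the
synthetic pipeline is self-contained; precomputed BLAST tabular files remain
the first-class path for real platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .types import AlignmentHit, TranscriptRecord

WORD_SIZE = 11
MATCH = 2
MISMATCH = -3
GAP_OPEN = 5
GAP_EXTEND = 2  # a gap of length k costs GAP_OPEN + k * GAP_EXTEND

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment: score, column count and substitution count."""

    score: float
    align_length: int
    mismatches: int
    strand: str = "+"


def _query_words(query: str) -> list[str]:
    return [
        query[i : i + WORD_SIZE]
        for i in range(len(query) - WORD_SIZE + 1)
        if "N" not in query[i : i + WORD_SIZE]
    ]


def _seed_window(
    query: str, subject: str, words: Optional[list[str]] = None
) -> Optional[tuple[int, int]]:
    """Subject interval covering all exact WORD_SIZE seed matches, padded by
    one query length on each side; ``None`` when no seed exists."""
    if len(query) < WORD_SIZE or len(subject) < WORD_SIZE:
        return None
    if words is None:
        words = _query_words(query)
    lo, hi = None, None
    for w in words:
        first = subject.find(w)
        if first < 0:
            continue
        lo = first if lo is None else min(lo, first)
        last = subject.rfind(w)
        hi = last if hi is None else max(hi, last)
    if lo is None:
        return None
    pad = len(query)
    return max(0, lo - pad), min(len(subject), hi + WORD_SIZE + pad)


def smith_waterman(query: str, subject: str) -> LocalAlignment:
    """Affine-gap local alignment with full traceback (Gotoh recurrences).

    Returns the best-scoring alignment; ``align_length`` counts all alignment
    columns including gaps, ``mismatches`` counts substitution columns.
    ``N`` never matches anything.
    """
    n, m = len(query), len(subject)
    NEG = float("-inf")
    open1 = GAP_OPEN + GAP_EXTEND
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1, Mi = E[i], F[i], F[i - 1], M[i]
        for j in range(1, m + 1):
            sc = subject[j - 1]
            sub = MATCH if (qc == sc and qc != "N") else MISMATCH
            mij = Hi1[j - 1] + sub
            eij = max(Hi[j - 1] - open1, Ei[j - 1] - GAP_EXTEND)
            fij = max(Hi1[j] - open1, Fi1[j] - GAP_EXTEND)
            hij = max(0.0, mij, eij, fij)
            Mi[j], Ei[j], Fi[j], Hi[j] = mij, eij, fij, hij
            if hij > best:
                best, bi, bj = hij, i, j
    if best <= 0:
        return LocalAlignment(0.0, 0, 0)
    # traceback
    i, j = bi, bj
    length = 0
    mism = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            if H[i][j] == M[i][j]:
                state = "M"
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
            continue
        if state == "M":
            length += 1
            if not (query[i - 1] == subject[j - 1] and query[i - 1] != "N"):
                mism += 1
            i, j = i - 1, j - 1
            state = "H"
        elif state == "E":
            length += 1
            came_open = E[i][j] == H[i][j - 1] - open1
            j -= 1
            state = "H" if came_open else "E"
        else:  # F
            length += 1
            came_open = F[i][j] == H[i - 1][j] - open1
            i -= 1
            state = "H" if came_open else "F"
    return LocalAlignment(best, length, mism)


def best_local_hit(
    probe_seq: str,
    transcript_seq: str,
    words: Optional[list[str]] = None,
) -> Optional[LocalAlignment]:
    """Best seeded local alignment of a probe against one transcript,
    searching both strands; ``None`` when no 11-mer seed exists."""
    best: Optional[LocalAlignment] = None
    if words is None:
        words = _query_words(probe_seq)
    for strand, subj in (("+", transcript_seq), ("-", reverse_complement(transcript_seq))):
        window = _seed_window(probe_seq, subj, words)
        if window is None:
            continue
        lo, hi = window
        aln = smith_waterman(probe_seq, subj[lo:hi])
        if aln.score <= 0:
            continue
        aln = LocalAlignment(aln.score, aln.align_length, aln.mismatches, strand)
        if best is None or (aln.score, aln.align_length) > (best.score, best.align_length):
            best = aln
    return best


def best_cross_species_hit(
    probe, transcripts: Sequence[TranscriptRecord]
) -> Optional[AlignmentHit]:
    """Highest-scoring hit of a probe against a (cross-species) transcriptome.

    Ties break by larger alignment length, then lexicographically smaller
    transcript id; an empty transcriptome or absence of any seed yields
    ``None``.
    """
    probe_seq = probe.sequence if hasattr(probe, "sequence") else str(probe)
    probe_id = getattr(probe, "probe_id", "query")
    words = _query_words(probe_seq)
    best_hit: Optional[AlignmentHit] = None
    for t in transcripts:
        aln = best_local_hit(probe_seq, t.sequence, words)
        if aln is None:
            continue
        hit = AlignmentHit(
            probe_id, t.transcript_id, aln.align_length, aln.mismatches, aln.score, t.species
        )
        if best_hit is None or _better(hit, best_hit):
            best_hit = hit
    return best_hit


def _better(a: AlignmentHit, b: AlignmentHit) -> bool:
    ka = (a.score, a.align_length)
    kb = (b.score, b.align_length)
    if ka != kb:
        return ka > kb
    return a.subject_id < b.subject_id


def best_hits_for_probes(
    probes: Iterable, transcripts: Sequence[TranscriptRecord]
) -> dict[str, AlignmentHit]:
    """Map probe id -> best cross-species hit (probes without a hit omitted)."""
    out: dict[str, AlignmentHit] = {}
    for p in probes:
        hit = best_cross_species_hit(p, transcripts)
        if hit is not None:
            out[p.probe_id] = hit
    return out
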