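"""Global pairwise DNA alignment and the percent-identity statistic.

All cluster, unit and variant comparisons in the package run through the
same needle-style global aligner: affine gap penalties, free end gaps,
match +5 / mismatch −4 / gap open 10 / gap extend 0.5 (the EMBOSS needle
defaults).  Percent identity is identities over total alignment columns,
gap columns included in the denominator, which is the "Identity" figure
needle prints.

The heavy lifting is delegated to :class:`Bio.Align.PairwiseAligner`
(C implementation); this module owns the scoring conventions and the
statistic definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align as _BioAlign

from cystra.io import VALID_BASES

__all__ = [
    "ScoringScheme",
    "Alignment",
    "needleman_wunsch",
    "percent_identity",
    "identity_matrix",
    "local_align",
    "local_score",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring.  A gap of length k costs ``gap_open + k*gap_extend``."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment as two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def identities(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )


def _check_dna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"sequence {name} contains non-ACGTN symbols {sorted(bad)}")


@lru_cache(maxsize=8)
def _make_aligner(scoring: ScoringScheme, mode: str) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    if mode == "global" and not scoring.end_gaps_penalized:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def needleman_wunsch(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> Alignment:
    """Optimal global alignment of two DNA strings under affine gap costs.

    The first optimal traceback reported by the aligner is returned;
    co-optimal alignments share the score, so the identity statistic can
    differ only within ties of identical score.
    """
    _check_dna(a, "a")
    _check_dna(b, "b")
    aligner = _make_aligner(scoring, "global")
    aln = aligner.align(a, b)[0]
    return Alignment(aligned_a=aln[0], aligned_b=aln[1], score=aln.score)


def nw_score(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Global alignment score only (no traceback; faster)."""
    _check_dna(a, "a")
    _check_dna(b, "b")
    return _make_aligner(scoring, "global").score(a, b)


def percent_identity(alignment: Alignment) -> float:
    """Percent identity: 100 × identities / alignment columns.

    Gap columns count in the denominator (EMBOSS needle convention).
    """
    if alignment.length == 0:
        raise ValueError("alignment has zero length")
    return 100.0 * alignment.identities / alignment.length


def pairwise_identity(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Percent identity of the optimal global alignment of two sequences."""
    return percent_identity(needleman_wunsch(a, b, scoring))


def identity_matrix(
    seqs: list[str], scoring: ScoringScheme = DEFAULT_SCORING
) -> np.ndarray:
    """Symmetric matrix of global-alignment percent identities.

    Each off-diagonal pair is aligned once; the diagonal is 100.0.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("identity_matrix needs at least two sequences")
    for i, s in enumerate(seqs):
        if not s:
            raise ValueError(f"sequence at index {i} is empty")
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(seqs[i], seqs[j], scoring)
            mat[i, j] = mat[j, i] = pid
    return mat


def local_align(ref: str, query: str, scoring: ScoringScheme = DEFAULT_SCORING):
    """Best local (Smith–Waterman) alignment of query against ref.

    Returns ``(score, ref_start, ref_end, identities, columns)`` where
    ref_start/ref_end bound the aligned region on ``ref`` (0-based
    half-open).  Used by the expression module for read assignment and
    precursor-extent checks.
    """
    _check_dna(ref, "ref")
    _check_dna(query, "query")
    aligner = _make_aligner(scoring, "local")
    alns = aligner.align(ref, query)
    aln = alns[0]
    ref_start = int(aln.coordinates[0][0])
    ref_end = int(aln.coordinates[0][-1])
    a, b = aln[0], aln[1]
    idents = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return aln.score, ref_start, ref_end, idents, len(a)


def local_score(ref: str, query: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Best local alignment score only (no traceback)."""
    return _make_aligner(scoring, "local").score(ref, query)
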