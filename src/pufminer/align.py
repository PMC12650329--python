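"""Pairwise protein alignment kernel.

Global (Needleman–Wunsch) and local (Smith–Waterman) affine-gap alignment,
identity conventions, and Karlin–Altschul bit score / E-value / alignment
score.  The "alignment score" (AS) used to weight sequence-similarity-network
edges is defined here as ``max(0, -log10(E))``, so an AS threshold of 80
keeps pairs whose alignment E-value is at most 1e-80.

Dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`
(C implementation); this module fixes the scoring conventions and wraps the
result in a small value object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: residues accepted in input sequences (X = ambiguity)
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: standard gapped BLOSUM62 statistical parameters
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

#: BLAST-style affine penalties: a gap of length k costs open + k * extend
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

#: E-values are floored here before taking log10, to avoid overflow
E_VALUE_FLOOR = 1e-180


class AlignmentError(ValueError):
    """Raised for empty or non-protein input sequences."""


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise alignment.

    Coordinates are 1-based and inclusive on each input sequence; for an
    empty local alignment all coordinates are 0.
    """

    raw_score: float
    identities: int
    aligned_pairs: int
    alignment_length: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    len_a: int
    len_b: int
    bit_score: float
    e_value: float
    alignment_score: float

    @property
    def is_empty(self) -> bool:
        return self.alignment_length == 0


@lru_cache(maxsize=None)
def default_matrix() -> substitution_matrices.Array:
    """BLOSUM62, the default scoring matrix throughout the package."""
    return substitution_matrices.load("BLOSUM62")


def load_matrix(path_or_name: str) -> substitution_matrices.Array:
    """Load a substitution matrix by NCBI name or from a matrix text file."""
    try:
        return substitution_matrices.load(path_or_name)
    except FileNotFoundError:
        return substitution_matrices.read(path_or_name)


def _check_sequence(seq: str, which: str) -> None:
    if not seq:
        raise AlignmentError(f"{which} sequence is empty")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise AlignmentError(
            f"{which} sequence contains non-amino-acid characters: {sorted(bad)}"
        )


def _aligner(matrix, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix if matrix is not None else default_matrix()
    # BLAST convention: first gap residue costs open + extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def evalue_and_as(
    raw_score: float,
    m: int,
    n: int,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> tuple[float, float, float]:
    """Karlin–Altschul statistics for a raw alignment score.

    bit = (lambda * S - ln K) / ln 2;  E = m * n * 2**(-bit);
    AS = max(0, -log10 E) with E floored at :data:`E_VALUE_FLOOR`.
    """
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions m, n must be >= 1")
    if lam <= 0 or K <= 0:
        raise ValueError("Karlin-Altschul parameters lambda, K must be positive")
    bit = (lam * raw_score - math.log(K)) / math.log(2)
    # work in log space: log10 E = log10(m n) - bit * log10 2
    log10_e = math.log10(m) + math.log10(n) - bit * math.log10(2)
    log10_e = max(log10_e, math.log10(E_VALUE_FLOOR))
    e_value = 10.0 ** log10_e
    alignment_score = max(0.0, -log10_e)
    return bit, e_value, alignment_score


def _summarise(alignment, len_a: int, len_b: int, mn: int | None,
               lam: float, K: float) -> AlignmentResult:
    counts = alignment.counts()
    identities = counts.identities
    aligned_pairs = counts.identities + counts.mismatches
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        a_start = a_end = b_start = b_end = 0
        alignment_length = 0
    else:
        a_start = int(blocks_a[0][0]) + 1
        a_end = int(blocks_a[-1][1])
        b_start = int(blocks_b[0][0]) + 1
        b_end = int(blocks_b[-1][1])
        alignment_length = alignment.length
    raw = float(alignment.score)
    m_times_n = mn if mn is not None else len_a * len_b
    bit, e_value, as_score = evalue_and_as(raw, 1, m_times_n, lam, K)
    return AlignmentResult(
        raw_score=raw,
        identities=identities,
        aligned_pairs=aligned_pairs,
        alignment_length=alignment_length,
        a_start=a_start, a_end=a_end, b_start=b_start, b_end=b_end,
        len_a=len_a, len_b=len_b,
        bit_score=bit, e_value=e_value, alignment_score=as_score,
    )


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mn: int | None = None,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> AlignmentResult:
    """Optimal global affine-gap alignment of two protein sequences."""
    _check_sequence(a, "first")
    _check_sequence(b, "second")
    aligner = _aligner(matrix, gap_open, gap_extend, "global")
    alignment = aligner.align(a, b)[0]
    return _summarise(alignment, len(a), len(b), mn, lam, K)


def local_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mn: int | None = None,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment; empty result if no
    positive-scoring pair of substrings exists."""
    _check_sequence(a, "first")
    _check_sequence(b, "second")
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        best = None
    if best is None or best.score <= 0:
        m_times_n = mn if mn is not None else len(a) * len(b)
        bit, e_value, as_score = evalue_and_as(0.0, 1, m_times_n, lam, K)
        return AlignmentResult(0.0, 0, 0, 0, 0, 0, 0, 0, len(a), len(b),
                               bit, e_value, as_score)
    return _summarise(best, len(a), len(b), mn, lam, K)


def percent_identity(result: AlignmentResult, mode: str = "aligned_positions") -> float:
    """Identity fraction under one of three denominators.

    ``full_alignment``   identities / alignment columns (gaps included)
    ``aligned_positions`` identities / columns where both rows have a residue
    ``shorter_sequence`` identities / min(len a, len b)
    """
    if mode == "full_alignment":
        denom = result.alignment_length
    elif mode == "aligned_positions":
        denom = result.aligned_pairs
    elif mode == "shorter_sequence":
        denom = min(result.len_a, result.len_b)
    else:
        raise ValueError(f"unknown identity mode: {mode!r}")
    if denom == 0:
        raise ZeroDivisionError(f"identity undefined: zero denominator in mode {mode!r}")
    return result.identities / denom
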