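"""Position-specific scoring models built from seed alignments.

A :class:`ProfileModel` is the package's stand-in for a curated domain model
(the reaction-center L/M/D1/D2 family, or the OmpA-like peptidoglycan-binding
domain): a per-column log-odds table over the 20 amino acids, derived from a
seed multiple alignment with additive pseudocounts against a uniform
background.  Scanning is local affine-gap alignment of the profile against a
sequence, with iterated masked re-scans so that both domains of a fusion
protein are reported as separate non-overlapping hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dp import affine_dp
from .records import SeqRecordX
from .simulate import AA, _AA_INDEX

#: gap penalties for profile-sequence alignment, in bits
PROFILE_GAP_OPEN = 7.0
PROFILE_GAP_EXTEND = 1.0

#: default acceptance threshold (bits) for a domain hit
DEFAULT_BIT_THRESHOLD = 40.0

MIN_PROFILE_LENGTH = 10


@dataclass
class DomainHit:
    """A profile match on a sequence (1-based, inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    score: float                 # bits
    which_profile: str           # e.g. "RC_domain" | "OmpA_like"
    profile_start: int = 0       # matched profile columns, 1-based
    profile_end: int = 0

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ProfileModel:
    """Log-odds scoring profile over match columns of a seed alignment."""

    log_odds: np.ndarray         # (length, 20), bits
    pseudocount_weight: float
    source_msa_id: str
    name: str = "RC_domain"
    match_columns: list = field(default_factory=list)  # original MSA columns

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        return "".join(AA[int(i)] for i in np.argmax(self.log_odds, axis=1))


def build_profile(seed_msa: list[SeqRecordX], pseudocount_weight: float = 1.0,
                  name: str = "RC_domain",
                  background: np.ndarray | None = None) -> ProfileModel:
    """Build a PSSM from a seed alignment.

    Match columns are those with at most 50 % gaps.  Column frequencies use
    additive pseudocounts: ``f_a = (c_a + w * q_a) / (n + w)`` with uniform
    background ``q_a = 1/20`` unless given; scores are ``log2(f_a / q_a)``.
    """
    if len(seed_msa) < 3:
        raise ValueError("seed alignment needs at least 3 sequences")
    ncol = len(seed_msa[0].sequence)
    if any(len(r.sequence) != ncol for r in seed_msa):
        raise ValueError("seed alignment rows have inconsistent column counts")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount weight must be >= 0")
    q = background if background is not None else np.full(20, 1 / 20)
    rows = [r.sequence.upper() for r in seed_msa]
    cols, log_odds = [], []
    for j in range(ncol):
        column = [row[j] for row in rows]
        residues = [c for c in column if c in _AA_INDEX]
        gap_fraction = 1 - len(residues) / len(column)
        if gap_fraction > 0.5:
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[_AA_INDEX[c]] += 1
        freqs = (counts + pseudocount_weight * q) / (len(residues) + pseudocount_weight)
        log_odds.append(np.log2(freqs / q))
        cols.append(j)
    if len(cols) < MIN_PROFILE_LENGTH:
        raise ValueError(f"profile too short: {len(cols)} match columns "
                         f"(minimum {MIN_PROFILE_LENGTH})")
    return ProfileModel(log_odds=np.array(log_odds),
                        pseudocount_weight=pseudocount_weight,
                        source_msa_id=seed_msa[0].seq_id, name=name,
                        match_columns=cols)


def _cell_scores(seq: str, profile: ProfileModel) -> np.ndarray:
    """(len(seq), profile.length) log-odds matrix; X scores 0 everywhere."""
    L = profile.log_odds  # (m, 20)
    idx = np.array([_AA_INDEX.get(c, -1) for c in seq])
    S = np.where(idx[:, None] >= 0, L.T[idx.clip(min=0)], 0.0)
    return S


def scan_profile(seq: SeqRecordX | str, profile: ProfileModel,
                 bit_threshold: float = DEFAULT_BIT_THRESHOLD,
                 max_hits: int = 4) -> list[DomainHit]:
    """Find non-overlapping profile hits scoring at least ``bit_threshold``.

    After each hit the matched sequence region is masked and the scan is
    repeated, so a two-domain fusion yields two hits.  Hits are returned
    sorted by start coordinate.
    """
    record = seq if isinstance(seq, SeqRecordX) else SeqRecordX("query", seq)
    if not record.sequence:
        raise ValueError("cannot scan an empty sequence")
    S = _cell_scores(record.sequence, profile)
    hits: list[DomainHit] = []
    masked = S.copy()
    for _ in range(max_hits):
        score, path = affine_dp(masked, PROFILE_GAP_OPEN, PROFILE_GAP_EXTEND, "local")
        if not path or score < bit_threshold:
            break
        rows = [p[0] for p in path if p[0] is not None]
        cols = [p[1] for p in path if p[1] is not None]
        hit = DomainHit(seq_id=record.seq_id, start=rows[0] + 1, end=rows[-1] + 1,
                        score=float(score), which_profile=profile.name,
                        profile_start=cols[0] + 1, profile_end=cols[-1] + 1)
        hits.append(hit)
        masked[rows[0]:rows[-1] + 1, :] = -1e30
    hits.sort(key=lambda h: h.start)
    return hits
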