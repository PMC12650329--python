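"""Homolog identification: profile hits, pairwise seed hits, fusion splitting.

A protein enters the homolog set if the RC-domain profile finds a hit at or
above the bit threshold OR its best local alignment against any seed query
reaches the pairwise alignment-score threshold.  The union matters: highly
divergent full-length homologs can fall below the domain-model threshold yet
remain recognisable by direct pairwise comparison — the reason the published
search combined a domain model with a protein–protein search.

Fusion proteins (two RC domains in one ORF) are split into their N-terminal
(PufL-like) and C-terminal (PufM-like) domain sequences, labeled ``N_`` and
``C_`` strictly by sequence order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

from .align import local_align
from .profiles import DEFAULT_BIT_THRESHOLD, DomainHit, ProfileModel, scan_profile
from .records import SeqRecordX

log = logging.getLogger(__name__)

#: default pairwise route threshold on the alignment score (-log10 E)
DEFAULT_PAIRWISE_AS = 8.0


@dataclass
class HomologSet:
    """Proteins identified as RC homologs, with per-route provenance."""

    members: dict = field(default_factory=dict)       # seq_id -> SeqRecordX
    by_profile: set = field(default_factory=set)
    by_pairwise: set = field(default_factory=set)
    domain_hits: dict = field(default_factory=dict)   # seq_id -> [DomainHit]
    fusion_ids: set = field(default_factory=set)      # >= 2 domain hits

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.members

    def __len__(self) -> int:
        return len(self.members)


def find_homologs(proteins: list[SeqRecordX],
                  profile: ProfileModel,
                  seed_queries: list[SeqRecordX],
                  profile_threshold: float = DEFAULT_BIT_THRESHOLD,
                  pairwise_threshold: float = DEFAULT_PAIRWISE_AS) -> HomologSet:
    """Union of profile-domain hits and pairwise seed-query hits."""
    if not seed_queries:
        raise ValueError("at least one seed query is required")
    out = HomologSet()
    for p in proteins:
        hits = scan_profile(p, profile, bit_threshold=profile_threshold)
        profile_hit = bool(hits)
        pairwise_hit = any(
            local_align(p.sequence, q.sequence).alignment_score >= pairwise_threshold
            for q in seed_queries)
        if not (profile_hit or pairwise_hit):
            continue
        out.members[p.seq_id] = p
        if profile_hit:
            out.by_profile.add(p.seq_id)
        if pairwise_hit:
            out.by_pairwise.add(p.seq_id)
        out.domain_hits[p.seq_id] = hits
        if len(hits) >= 2:
            out.fusion_ids.add(p.seq_id)
    return out


def split_fusion_domains(record: SeqRecordX,
                         hits: list[DomainHit]) -> list[SeqRecordX]:
    """Cut a protein into per-domain sequences.

    Two hits: ids prefixed ``N_`` (first in sequence order) and ``C_``; one
    hit: the record passes through unlabeled (full sequence kept).  More than
    two hits: the best two by score are kept with a warning.  The returned
    records carry 1-based parent coordinates.
    """
    if not hits:
        return [record]
    hits = sorted(hits, key=lambda h: h.start)
    for a, b in zip(hits, hits[1:]):
        if a.overlaps(b):
            raise RuntimeError(
                f"overlapping domain hits on {record.seq_id}: "
                f"{a.start}-{a.end} vs {b.start}-{b.end} (resolve upstream)")
    if len(hits) > 2:
        log.warning("%s has %d domain hits; keeping best two by score",
                    record.seq_id, len(hits))
        hits = sorted(sorted(hits, key=lambda h: -h.score)[:2],
                      key=lambda h: h.start)
    if len(hits) == 1:
        return [record]
    out = []
    for prefix, hit in zip(("N_", "C_"), hits):
        out.append(dataclasses.replace(
            record,
            seq_id=f"{prefix}{record.seq_id}",
            sequence=record.sequence[hit.start - 1:hit.end],
            parent_id=record.seq_id,
            parent_start=hit.start,
            parent_end=hit.end))
    return out


def split_all_fusions(homologs: HomologSet) -> list[SeqRecordX]:
    """Apply :func:`split_fusion_domains` across a homolog set, returning the
    sequence set used downstream (domains for fusions, full sequences
    otherwise), in deterministic id order."""
    out = []
    for seq_id in sorted(homologs.members):
        out.extend(split_fusion_domains(homologs.members[seq_id],
                                        homologs.domain_hits.get(seq_id, [])))
    return out


@dataclass
class RescueHit:
    seq_id: str
    bin_id: str | None
    alignment_score: float
    already_member: bool


def rescue_scan(proteins: list[SeqRecordX],
                divergent_query: SeqRecordX,
                low_threshold: float = 5.0,
                homologs: HomologSet | None = None) -> list[RescueHit]:
    """Low-threshold sweep with a divergent query to catch full-length
    homologs dropped earlier (e.g. edgeless network singletons).

    Returns all proteins whose local alignment against the query reaches
    ``low_threshold``, annotated with whether they were already identified.
    """
    out = []
    for p in proteins:
        as_score = local_align(p.sequence, divergent_query.sequence).alignment_score
        if as_score >= low_threshold:
            out.append(RescueHit(
                seq_id=p.seq_id, bin_id=p.bin_id, alignment_score=as_score,
                already_member=(homologs is not None and p.seq_id in homologs)))
    out.sort(key=lambda h: (-h.alignment_score, h.seq_id))
    return out
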