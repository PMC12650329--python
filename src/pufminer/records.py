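"""Shared record types: sequences with provenance and contig gene features."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SeqRecordX:
    """A protein (or DNA) sequence with metagenomic provenance.

    Coordinates, when set, are 1-based inclusive positions on the parent
    sequence the record was cut from (e.g. a domain on a fusion protein).
    """

    seq_id: str
    sequence: str
    bin_id: str | None = None
    taxon: str | None = None
    hot_spring: bool | None = None
    parent_id: str | None = None
    parent_start: int | None = None
    parent_end: int | None = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A gene interval on a contig (1-based, inclusive, stranded)."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    label: str = "other"
    domain_annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.gene_id}: bad strand {self.strand!r}")


#: controlled vocabulary for puf-gene labels in neighborhood analysis
GENE_LABELS = {"pufL", "pufM", "pufLM_fusion", "pufA", "pufB", "pufC", "other"}
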