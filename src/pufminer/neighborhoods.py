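"""Gene-neighborhood extraction and puf operon architecture classification.

Photosynthesis gene clusters come in a handful of recognisable arrangements:
a single colocated operon (pufB-pufA-pufL-pufM(-pufC)), a split layout with
pufL+pufM at one locus and pufB+pufA+pufC at another, an alternative
colocated arrangement without pufC, single-ORF PufL-PufM fusions, and
OmpA-like terminal-domain fusions on PufM or PufC.  Adjacency means
consecutive genes on the same strand with an intergenic gap of at most
``max_gap_bp`` (default 500 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .profiles import DEFAULT_BIT_THRESHOLD, DomainHit, ProfileModel, scan_profile
from .records import GeneFeature, SeqRecordX

ARCHITECTURE_CLASSES = (
    "A_colocated_pufBALMC",
    "B_split_LM_and_BAC",
    "C_cluster3_arrangement",
    "D_LM_fusion",
    "E_ompA_fusion",
    "fragment_or_unknown",
)

#: short class codes used in generator truth and reports
SHORT = {"A_colocated_pufBALMC": "A", "B_split_LM_and_BAC": "B",
         "C_cluster3_arrangement": "C", "D_LM_fusion": "D",
         "E_ompA_fusion": "E", "fragment_or_unknown": "?"}

DEFAULT_MAX_GAP_BP = 500
DEFAULT_WINDOW_GENES = 10


@dataclass
class Neighborhood:
    """Genes around an anchor on one contig, in genomic coordinate order."""

    anchor: GeneFeature
    features: list                  # including the anchor
    truncated_left: bool = False    # window hit the contig start
    truncated_right: bool = False

    @property
    def labels(self) -> list:
        return [f.label for f in self.features]


def extract_neighborhood(features: list[GeneFeature], anchor_gene: str,
                         window_genes: int = DEFAULT_WINDOW_GENES) -> Neighborhood:
    """Up to ``window_genes`` genes on each side of the anchor, same contig.

    The window never crosses a contig; a side cut short by the contig end is
    flagged."""
    anchor = next((f for f in features if f.gene_id == anchor_gene), None)
    if anchor is None:
        raise ValueError(f"anchor gene {anchor_gene!r} not found")
    contig = sorted((f for f in features if f.contig_id == anchor.contig_id),
                    key=lambda f: (f.start, f.gene_id))
    idx = next(i for i, f in enumerate(contig) if f.gene_id == anchor_gene)
    lo = max(0, idx - window_genes)
    hi = min(len(contig), idx + window_genes + 1)
    return Neighborhood(
        anchor=anchor,
        features=contig[lo:hi],
        truncated_left=(idx - lo) < window_genes and lo == 0,
        truncated_right=(hi - 1 - idx) < window_genes and hi == len(contig),
    )


def adjacency_runs(features: list[GeneFeature],
                   max_gap_bp: int = DEFAULT_MAX_GAP_BP) -> list:
    """Maximal runs of consecutive same-strand genes with small intergenic
    gaps, per contig — the operational definition of an operon candidate."""
    runs = []
    by_contig: dict[str, list] = {}
    for f in features:
        by_contig.setdefault(f.contig_id, []).append(f)
    for contig_id in sorted(by_contig):
        genes = sorted(by_contig[contig_id], key=lambda f: (f.start, f.gene_id))
        current = [genes[0]]
        for prev, nxt in zip(genes, genes[1:]):
            gap = nxt.start - prev.end - 1
            if nxt.strand == prev.strand and gap <= max_gap_bp:
                current.append(nxt)
            else:
                runs.append(current)
                current = [nxt]
        runs.append(current)
    return runs


@dataclass
class ArchitectureCall:
    architecture: str
    evidence: list = field(default_factory=list)    # gene ids supporting it

    @property
    def short(self) -> str:
        return SHORT[self.architecture]


def classify_architecture(features: list[GeneFeature],
                          max_gap_bp: int = DEFAULT_MAX_GAP_BP) -> ArchitectureCall:
    """Classify one genome/bin's puf arrangement.  Total: always returns a
    class, falling back to ``fragment_or_unknown``.

    Priority: fusion ORF (D), OmpA-like terminal annotation on pufM/pufC
    (E), full colocated operon (A), split two-locus layout (B), colocated
    pufL+pufM without the A/B signatures (C)."""
    fusions = [f for f in features if f.label == "pufLM_fusion"]
    if fusions:
        return ArchitectureCall("D_LM_fusion", [f.gene_id for f in fusions])
    ompa = [f for f in features if f.label in {"pufM", "pufC"}
            and any(a.startswith("OmpA_like") for a in f.domain_annotations)]
    if ompa:
        return ArchitectureCall("E_ompA_fusion", [f.gene_id for f in ompa])
    runs = adjacency_runs(features, max_gap_bp)
    run_labels = [set(f.label for f in run) for run in runs]

    def evidence(run, wanted):
        return [f.gene_id for f in run if f.label in wanted]

    for run, labels in zip(runs, run_labels):
        if {"pufB", "pufA", "pufL", "pufM"} <= labels:
            return ArchitectureCall("A_colocated_pufBALMC",
                                    evidence(run, {"pufB", "pufA", "pufL",
                                                   "pufM", "pufC"}))
    lm_runs = [run for run, labels in zip(runs, run_labels)
               if {"pufL", "pufM"} <= labels]
    bac_runs = [run for run, labels in zip(runs, run_labels)
                if {"pufB", "pufA", "pufC"} <= labels]
    if lm_runs and bac_runs and lm_runs[0] is not bac_runs[0]:
        return ArchitectureCall("B_split_LM_and_BAC",
                                evidence(lm_runs[0], {"pufL", "pufM"})
                                + evidence(bac_runs[0], {"pufB", "pufA", "pufC"}))
    if lm_runs:
        return ArchitectureCall("C_cluster3_arrangement",
                                evidence(lm_runs[0], {"pufL", "pufM"}))
    return ArchitectureCall("fragment_or_unknown", [])


def detect_terminal_domain(protein: SeqRecordX, ompa_profile: ProfileModel,
                           terminus: str = "C",
                           window_fraction: float = 0.35,
                           bit_threshold: float = DEFAULT_BIT_THRESHOLD,
                           ) -> tuple[bool, DomainHit | None]:
    """Is there a profile hit lying wholly within the terminal window?

    ``terminus`` is ``"N"`` or ``"C"``; the window is the first or last
    ``window_fraction`` of the sequence.  Returns (flag, best such hit)."""
    if terminus not in {"N", "C"}:
        raise ValueError("terminus must be 'N' or 'C'")
    n = len(protein.sequence)
    window = max(1, int(round(window_fraction * n)))
    hits = scan_profile(protein, ompa_profile, bit_threshold=bit_threshold)
    in_window = []
    for h in hits:
        if terminus == "N" and h.end <= window:
            in_window.append(h)
        elif terminus == "C" and h.start >= n - window + 1:
            in_window.append(h)
    if not in_window:
        return False, None
    best = max(in_window, key=lambda h: h.score)
    return True, best
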