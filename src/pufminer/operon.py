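"""Synthetic-operon design: codon optimization, assembly, translation, mass.

A heterologous RC operon is designed by reverse-translating each protein
with the host's codon-usage table (either always the most frequent codon,
or codons drawn proportionally to host usage), interspacing the coding
sequences with ribosome-binding-site and spacer elements, and optionally
inserting a 6-His tag immediately after a gene's initiator methionine.
Masses are average (not monoisotopic) protein masses, matching what one
reads off an SDS-PAGE gel annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

HIS_TAG = "HHHHHH"

#: default ribosome binding site / spacer elements (Shine-Dalgarno core)
DEFAULT_RBS = "AGGAGGTTTGGA"
DEFAULT_SPACER = "CTAGCATAACCCCTTGGGGCCTCTAAACGGGTCTTGAGGGGTTTTTTG"


class TranslationError(ValueError):
    """Raised for frame or internal-stop problems."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon usage for one host.

    ``frequencies`` maps amino acid (one letter, plus '*' for stop) to a
    dict codon -> relative frequency; frequencies per amino acid sum to 1.
    """

    host: str
    frequencies: dict

    def validate(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[11]
        for aa, codons in self.frequencies.items():
            if not codons:
                raise ValueError(f"no codons for amino acid {aa}")
            total = sum(codons.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"codon frequencies for {aa} sum to {total}")
            for codon in codons:
                translated = "*" if codon in table.stop_codons \
                    else table.forward_table.get(codon)
                if translated != aa:
                    raise ValueError(f"codon {codon} does not encode {aa}")

    def most_frequent(self, aa: str) -> str:
        codons = self.frequencies[aa]
        return max(sorted(codons), key=lambda c: codons[c])

    @classmethod
    def read_tsv(cls, path: str | Path, host: str = "") -> "CodonUsageTable":
        df = pd.read_csv(path, sep="\t")
        freqs: dict[str, dict] = {}
        for _, row in df.iterrows():
            freqs.setdefault(row["amino_acid"], {})[row["codon"]] = float(row["fraction"])
        out = cls(host=host or str(path), frequencies=freqs)
        out.validate()
        return out

    def write_tsv(self, path: str | Path) -> None:
        rows = [{"amino_acid": aa, "codon": c, "fraction": f}
                for aa in sorted(self.frequencies)
                for c, f in sorted(self.frequencies[aa].items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _uniform_usage(host: str = "uniform") -> CodonUsageTable:
    table = CodonTable.unambiguous_dna_by_id[11]
    freqs: dict[str, dict] = {}
    for codon, aa in table.forward_table.items():
        freqs.setdefault(aa, {})[codon] = 0.0
    for codon in table.stop_codons:
        freqs.setdefault("*", {})[codon] = 0.0
    for aa, codons in freqs.items():
        for c in codons:
            codons[c] = 1.0 / len(codons)
    return CodonUsageTable(host=host, frequencies=freqs)


def high_gc_usage(host: str = "high-GC host") -> CodonUsageTable:
    """A synthetic stand-in usage table for a GC-rich alphaproteobacterial
    expression host: within each synonymous family, weight grows with codon
    GC content (softmax over GC count), mimicking the strong GC3 bias of
    such genomes.  This is a constructed table, not measured usage data."""
    base = _uniform_usage(host)
    freqs: dict[str, dict] = {}
    for aa, codons in base.frequencies.items():
        weights = {c: np.exp(2.0 * sum(1 for x in c if x in "GC")) for c in codons}
        total = sum(weights.values())
        freqs[aa] = {c: w / total for c, w in sorted(weights.items())}
    out = CodonUsageTable(host=host, frequencies=freqs)
    out.validate()
    return out


def codon_optimize(protein: str, usage: CodonUsageTable,
                   policy: str = "most_frequent",
                   seed: int | None = None,
                   add_stop: bool = True) -> str:
    """Reverse-translate ``protein`` under the host usage table.

    ``most_frequent`` always picks the host's top codon (deterministic);
    ``weighted_random`` draws codons proportionally to host usage (seeded).
    The CDS always translates back to the input protein exactly.
    """
    usage.validate()
    bad = [c for c in protein if c not in usage.frequencies or c == "*"]
    if bad:
        raise ValueError(f"unknown residues for codon optimization: {sorted(set(bad))}")
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein:
        if policy == "most_frequent":
            codons.append(usage.most_frequent(aa))
        elif policy == "weighted_random":
            options = sorted(usage.frequencies[aa])
            probs = np.array([usage.frequencies[aa][c] for c in options])
            codons.append(options[rng.choice(len(options), p=probs / probs.sum())])
        else:
            raise ValueError(f"unknown policy {policy!r}")
    if add_stop:
        codons.append(usage.most_frequent("*"))
    return "".join(codons)


def translate(cds: str, allow_alt_start: bool = True) -> str:
    """Standard-code (table 11) translation; the trailing stop is removed.

    An internal stop raises with its codon position; a length not divisible
    by 3 is an error.  GTG initiators are accepted (read as M) when
    ``allow_alt_start``."""
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    if not cds:
        raise TranslationError("empty CDS")
    start = cds[:3].upper()
    if start not in {"ATG", "GTG"} or (start == "GTG" and not allow_alt_start):
        raise TranslationError(f"unexpected start codon {start}")
    prot = str(Seq(cds).translate(table=11))
    if prot.startswith("V") and start == "GTG":
        prot = "M" + prot[1:]
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        pos = prot.index("*")
        raise TranslationError(f"internal stop codon at codon {pos + 1} "
                               f"(nt {3 * pos + 1})")
    return prot


def protein_mass(protein: str, kda: bool = True) -> float:
    """Average molecular mass (sum of residue masses plus one water);
    returned in kDa by default."""
    if not protein:
        raise ValueError("empty protein")
    mass = molecular_weight(protein, seq_type="protein", monoisotopic=False)
    return mass / 1000.0 if kda else mass


# ---------------------------------------------------------------------------
# operon assembly


@dataclass
class OperonGene:
    name: str
    protein: str
    rbs: str = DEFAULT_RBS
    his_tag_after_start: bool = False


@dataclass
class OperonSpec:
    genes: list                     # of OperonGene
    spacer: str = DEFAULT_SPACER
    usage: CodonUsageTable = field(default_factory=high_gc_usage)
    policy: str = "most_frequent"
    seed: int | None = None

    def validate(self) -> None:
        if not self.genes:
            raise ValueError("operon needs at least one gene")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in operon spec")
        for g in self.genes:
            if not g.protein.startswith("M"):
                raise ValueError(f"gene {g.name}: protein must start with M")
            if not g.rbs:
                raise ValueError(f"gene {g.name}: missing RBS")


@dataclass
class OperonFeature:
    name: str
    kind: str                       # RBS | CDS | spacer
    start: int                      # 1-based inclusive
    end: int


@dataclass
class AssembledOperon:
    dna: str
    features: list                  # of OperonFeature

    def feature(self, name: str) -> OperonFeature:
        return next(f for f in self.features if f.name == name)

    def cds(self, gene_name: str) -> str:
        f = self.feature(f"{gene_name}_CDS")
        return self.dna[f.start - 1:f.end]


def assemble_operon(spec: OperonSpec) -> AssembledOperon:
    """RBS1+CDS1 + spacer + RBS2+CDS2 + ... with optional 6-His insertion
    immediately after a gene's initiator ATG.  The feature map partitions
    the construct with no gaps or overlaps."""
    spec.validate()
    parts: list[tuple[str, str, str]] = []   # (name, kind, seq)
    for k, gene in enumerate(spec.genes):
        if k > 0 and spec.spacer:
            parts.append((f"spacer_{k}", "spacer", spec.spacer))
        protein = gene.protein
        if gene.his_tag_after_start:
            protein = "M" + HIS_TAG + protein[1:]
        cds = codon_optimize(protein, spec.usage, spec.policy, spec.seed)
        parts.append((f"{gene.name}_RBS", "RBS", gene.rbs))
        parts.append((f"{gene.name}_CDS", "CDS", cds))
    dna = ""
    features = []
    pos = 1
    for name, kind, seq in parts:
        features.append(OperonFeature(name=name, kind=kind, start=pos,
                                      end=pos + len(seq) - 1))
        dna += seq
        pos += len(seq)
    return AssembledOperon(dna=dna, features=features)
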