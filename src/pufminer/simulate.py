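"""Synthetic Puf-family dataset generator.

Emulates the statistical structure of a hot-spring metagenome survey of
anoxygenic type-II reaction-center (RC) proteins, so that every downstream
stage — temperature curation, homolog search, sequence-similarity networks,
fusion splitting, phylogeny, operon-architecture classification and
uniqueness accounting — can be exercised against machine-readable ground
truth without any external downloads.

The model plants:

* two RC protein families ("PufL-like" and "PufM-like"), each organised into
  ``n_clades`` clades descended from a shared ancestral sequence;
* a more divergent outgroup pair ("PsbA-like" / "PsbD-like"), homologous to
  the RC families but far enough away to fall into separate network
  components — mirroring the photosystem-II D1/D2 relationship;
* PufL–PufM fusion proteins (single ORF, two RC domains joined by a fixed
  low-complexity linker) for a designated clade pair;
* fragments (records truncated to 30–60 % length), shuffled-composition
  decoys, one highly divergent full-length homolog, accessory puf genes
  (pufA/pufB/pufC) and OmpA-like terminal-domain fusions;
* metagenomic bins with collection temperatures (hot, cold-contaminant and
  missing) and contigs carrying five distinct puf operon architectures.

Amino-acid evolution is a fixed-length (no-indel) uniform replacement
process: along a branch of length ``b`` each site is replaced with
probability ``p = 1 - exp(-b)``, the replacement drawn uniformly from the
other 19 residues.  This keeps identities closed-form checkable: two leaves
whose path to their common ancestor is ``b`` each have expected per-site
identity ``(1-p)^2 + p^2/19``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .records import GeneFeature, SeqRecordX

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}

#: fixed low-complexity linker joining the two domains of a planted fusion
FUSION_LINKER = "GGSGGSGGSG"

HOT_SUBTYPE = "Thermal springs: Hot (42-90C)"
WARM_SUBTYPE = "Thermal springs: Warm (34-42C)"

ARCHITECTURES = ("A", "B", "C", "D", "E")


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic survey.

    Divergences are expected substitutions per site and must be ordered
    ``within < between < outgroup``; the family divergence (ancestor to
    family root) sits between the clade scale and the outgroup scale so that
    PufL-like and PufM-like sequences are recognisably homologous yet fall
    into separate network clusters.
    """

    n_clades_pufL: int = 4
    n_clades_pufM: int = 4
    seqs_per_clade: int = 6
    root_length: int = 300
    within_clade_divergence: float = 0.05
    between_clade_divergence: float = 0.6
    family_divergence: float = 0.5
    outgroup_divergence: float = 1.2
    fusion_clade_indices: frozenset = frozenset({1})
    fragment_fraction: float = 0.1
    missing_temp_fraction: float = 0.2
    temp_range_hot: tuple = (42.0, 90.0)
    temp_range_cold: tuple = (0.0, 42.0)
    architecture_mix: tuple = (("A", 0.2), ("B", 0.2), ("C", 0.2), ("D", 0.2), ("E", 0.2))
    n_outgroup_per_family: int = 3
    n_decoys: int = 10
    n_cold_bins: int = 3
    n_filler_bins: int = 5
    n_divergent: int = 1
    divergent_extra_divergence: float = 0.8
    novel_clade_indices: frozenset = frozenset({3})
    reference_divergence: float = 0.02
    accessory_divergence: float = 0.3
    ompa_length: int = 90
    ompa_divergence: float = 0.08
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("fragment_fraction", "missing_temp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not (0 < self.within_clade_divergence < self.between_clade_divergence
                < self.outgroup_divergence):
            raise ConfigurationError(
                "divergences must be ordered within < between < outgroup")
        if self.n_clades_pufL < 1 or self.n_clades_pufM < 1:
            raise ConfigurationError("clade counts must be >= 1")
        if self.seqs_per_clade < 1:
            raise ConfigurationError("seqs_per_clade must be >= 1")
        if self.root_length < 30:
            raise ConfigurationError("root_length must be >= 30 residues")
        n_paired = min(self.n_clades_pufL, self.n_clades_pufM)
        for idx in self.fusion_clade_indices:
            if not 0 <= idx < n_paired:
                raise ConfigurationError(
                    f"fusion clade index {idx} out of range [0, {n_paired})")
        weights = dict(self.architecture_mix)
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ConfigurationError("architecture_mix must be a non-negative "
                                     "distribution with positive total weight")
        if set(weights) - set(ARCHITECTURES):
            raise ConfigurationError(f"unknown architecture classes: "
                                     f"{set(weights) - set(ARCHITECTURES)}")
        n_max = max(self.n_clades_pufL, self.n_clades_pufM)
        for idx in self.novel_clade_indices:
            if not 0 <= idx < n_max:
                raise ConfigurationError(
                    f"novel clade index {idx} out of range [0, {n_max})")
        if not 0 <= self.reference_divergence < self.within_clade_divergence:
            raise ConfigurationError("reference_divergence must be small "
                                     "(below within_clade_divergence)")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SeqTruth:
    family: str                 # PufL | PufM | fusion | PsbA-like | PsbD-like | decoy | accessory | other
    clade: int = -1             # -1 = not clade-structured (decoys, divergent, accessory)
    domains: list = field(default_factory=list)    # RC-domain intervals, 1-based inclusive
    ompa_domain: tuple | None = None               # OmpA-like interval if planted
    fragment: bool = False
    divergent: bool = False


@dataclass
class TruthTable:
    sequences: dict            # seq_id -> SeqTruth
    bins: dict                 # bin_id -> true hot flag
    contigs: dict              # contig_id -> architecture class


@dataclass
class BinInfo:
    bin_id: str
    temperature_c: float | None
    ecosystem_subtype: str
    taxon: str
    source: str = "synthetic hot spring survey"


@dataclass
class SyntheticDataset:
    config: SimConfig
    bins: list                 # of BinInfo
    proteins: list             # of SeqRecordX
    features: list             # of GeneFeature
    truth: TruthTable
    rc_seed: list = field(default_factory=list)    # SeqRecordX, aligned (equal length)
    ompa_seed: list = field(default_factory=list)  # SeqRecordX, aligned
    references: list = field(default_factory=list)  # synthetic "known" proteins
    outgroup_refs: list = field(default_factory=list)  # seq_ids used to root

    def seq(self, seq_id: str) -> SeqRecordX:
        return self._index[seq_id]

    @property
    def _index(self) -> dict:
        idx = getattr(self, "_index_cache", None)
        if idx is None or len(idx) != len(self.proteins):
            idx = {p.seq_id: p for p in self.proteins}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def proteins_in_bin(self, bin_id: str) -> list:
        return [p for p in self.proteins if p.bin_id == bin_id]

    def seed_queries(self) -> list:
        """One non-fragment PufL, PufM and fusion record — the analogue of the
        published seed queries used for the pairwise homolog route."""
        picks = []
        for fam in ("PufL", "PufM", "fusion"):
            for p in self.proteins:
                t = self.truth.sequences[p.seq_id]
                if (t.family == fam and not t.fragment and not t.divergent
                        and t.ompa_domain is None):
                    picks.append(p)
                    break
        return picks

    def validate(self) -> None:
        bin_ids = {b.bin_id for b in self.bins}
        for p in self.proteins:
            if p.bin_id not in bin_ids:
                raise ValueError(f"protein {p.seq_id} maps to unknown bin {p.bin_id}")
        for sid, t in self.truth.sequences.items():
            n = len(self._index[sid].sequence)
            for (s, e) in t.domains:
                if not (1 <= s <= e <= n):
                    raise ValueError(f"truth domain {s}-{e} outside {sid} (len {n})")
            if t.family == "fusion" and not t.fragment and len(t.domains) != 2:
                raise ValueError(f"fusion {sid} must carry two domain intervals")


# ---------------------------------------------------------------------------
# sequence evolution


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def mutate_sequence(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    """Apply the uniform replacement process along one branch."""
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    if branch_length == 0:
        return seq
    p = 1.0 - np.exp(-branch_length)
    arr = np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    hit = rng.random(arr.size) < p
    # uniform over the other 19 residues: draw 0..18 and skip the current one
    draws = rng.integers(0, 19, size=arr.size)
    replaced = np.where(draws >= arr, draws + 1, draws)
    arr = np.where(hit, replaced, arr)
    return "".join(AA[i] for i in arr)


def simulate_guide_trees(config: SimConfig):
    """Family guide trees: one stem of length ``between_clade_divergence`` per
    clade, leaf branches of length ``within_clade_divergence``.

    Returns ``(tree_pufL, tree_pufM, outgroup_tree)`` as dendropy trees; the
    outgroup tree holds one PsbA-like and one PsbD-like clade.
    """
    config.validate()

    def family_tree(prefix: str, clade_names, n_leaves: int) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        for cname in clade_names:
            clade_node = dendropy.Node(edge_length=config.between_clade_divergence)
            tree.seed_node.add_child(clade_node)
            for j in range(n_leaves):
                leaf = dendropy.Node(edge_length=config.within_clade_divergence)
                leaf.taxon = taxa.new_taxon(label=f"{cname}_s{j}")
                clade_node.add_child(leaf)
        return tree

    tree_l = family_tree("L", [f"L_c{i}" for i in range(config.n_clades_pufL)],
                         config.seqs_per_clade)
    tree_m = family_tree("M", [f"M_c{i}" for i in range(config.n_clades_pufM)],
                         config.seqs_per_clade)
    tree_og = family_tree("OG", ["OGA", "OGD"], config.n_outgroup_per_family)
    return tree_l, tree_m, tree_og


def evolve_along_tree(tree: dendropy.Tree, root_seq: str, seed: int) -> dict:
    """Evolve ``root_seq`` down ``tree``; returns ``{leaf_label: sequence}``.

    One replacement draw per branch in a fixed preorder traversal, so output
    is deterministic per seed.
    """
    bad = set(root_seq) - set(AA)
    if not root_seq or bad:
        raise ValueError(f"root sequence empty or contains non-amino-acid "
                         f"characters: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        b = node.edge.length or 0.0
        child_seq = mutate_sequence(parent_seq, b, rng)
        seqs[id(node)] = child_seq
        if node.is_leaf():
            out[node.taxon.label] = child_seq
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def _allocate_architectures(n: int, mix: dict, rng: np.random.Generator) -> list:
    """Deterministic largest-remainder allocation of architectures over the
    non-fusion genomes, then an rng shuffle.  Guarantees every class with
    positive weight appears whenever counts allow."""
    classes = [c for c in ("A", "B", "C", "E") if mix.get(c, 0) > 0]
    if classes:
        weights = np.array([mix[c] for c in classes], dtype=float)
    else:  # all weight on D; non-fusion genomes fall back to colocated operons
        classes, weights = ["A"], np.array([1.0])
    weights = weights / weights.sum()
    exact = weights * n
    counts = np.floor(exact).astype(int)
    order = np.argsort(-(exact - counts))
    for k in order[: n - counts.sum()]:
        counts[k] += 1
    out = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(out)
    return out


def _truncate_fragment(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Keep a contiguous 30–60 % window; returns (fragment, 1-based offset)."""
    frac = rng.uniform(0.3, 0.6)
    keep = max(1, int(round(frac * len(seq))))
    start = int(rng.integers(0, len(seq) - keep + 1))
    return seq[start:start + keep], start + 1


def _clip_domains(domains, offset: int, length: int, min_keep: int = 30):
    """Re-express truth domains on a fragment window; drop slivers."""
    out = []
    lo, hi = offset, offset + length - 1
    for (s, e) in domains:
        cs, ce = max(s, lo), min(e, hi)
        if ce - cs + 1 >= min_keep:
            out.append((cs - offset + 1, ce - offset + 1))
    return out


class _GenomeLayout:
    """Helper accumulating contigs/features/proteins for one bin."""

    def __init__(self, bin_id: str, taxon: str, hot: bool):
        self.bin_id = bin_id
        self.taxon = taxon
        self.hot = hot
        self.features: list[GeneFeature] = []
        self.proteins: list[SeqRecordX] = []
        self.contig_counter = 0

    def new_contig(self) -> str:
        self.contig_counter += 1
        return f"{self.bin_id}_c{self.contig_counter}"

    def add_contig(self, genes, strand: str = "+", gap: int = 50) -> str:
        """genes: list of (gene_id, label, protein_seq_or_None, domain_annotations)."""
        contig = self.new_contig()
        pos = 101
        for gene_id, label, prot, annots in genes:
            length_nt = 3 * (len(prot) + 1) if prot else 300
            self.features.append(GeneFeature(
                contig_id=contig, gene_id=gene_id, start=pos,
                end=pos + length_nt - 1, strand=strand, label=label,
                domain_annotations=list(annots)))
            if prot is not None:
                self.proteins.append(SeqRecordX(
                    seq_id=gene_id, sequence=prot, bin_id=self.bin_id,
                    taxon=self.taxon, hot_spring=self.hot))
            pos += length_nt + gap
        return contig


def generate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic survey for ``config`` (defaults are the
    study conditions).  Byte-deterministic for a fixed config."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    # --- evolve the protein families ------------------------------------
    ancestor = random_protein(config.root_length, rng)
    l_root = mutate_sequence(ancestor, config.family_divergence, rng)
    m_root = mutate_sequence(ancestor, config.family_divergence, rng)
    og_root = mutate_sequence(ancestor, config.outgroup_divergence, rng)
    tree_l, tree_m, tree_og = simulate_guide_trees(config)
    seed_l, seed_m, seed_og = (int(s) for s in
                               rng.integers(0, 2**31 - 1, size=3))
    leaves_l = evolve_along_tree(tree_l, l_root, seed_l)
    leaves_m = evolve_along_tree(tree_m, m_root, seed_m)
    leaves_og = evolve_along_tree(tree_og, og_root, seed_og)

    ompa_root = random_protein(config.ompa_length, rng)
    accessory_roots = {
        "pufB": random_protein(50, rng),
        "pufA": random_protein(60, rng),
        "pufC": random_protein(330, rng),
    }

    def ompa_instance() -> str:
        return mutate_sequence(ompa_root, config.ompa_divergence, rng)

    def accessory(label: str) -> str:
        return mutate_sequence(accessory_roots[label], config.accessory_divergence, rng)

    truth_seqs: dict[str, SeqTruth] = {}
    layouts: list[_GenomeLayout] = []
    arch_truth: dict[str, str] = {}

    n_paired = min(config.n_clades_pufL, config.n_clades_pufM)
    fusion_clades = set(config.fusion_clade_indices)
    nonfusion = [(i, j) for i in range(n_paired) for j in range(config.seqs_per_clade)
                 if i not in fusion_clades]
    arch_assign = dict(zip(nonfusion, _allocate_architectures(
        len(nonfusion), dict(config.architecture_mix), rng)))

    def taxon_for_clade(i: int) -> str:
        return ("Pseudomonadota" if i == 0 else "Chloroflexota")

    bin_counter = 0

    def new_layout(taxon: str) -> _GenomeLayout:
        nonlocal bin_counter
        lay = _GenomeLayout(f"bin_{bin_counter:03d}", taxon, hot=True)
        bin_counter += 1
        layouts.append(lay)
        return lay

    # --- puf genomes -----------------------------------------------------
    for i in range(n_paired):
        for j in range(config.seqs_per_clade):
            lay = new_layout(taxon_for_clade(i))
            g = lay.bin_id
            l_seq = leaves_l[f"L_c{i}_s{j}"]
            m_seq = leaves_m[f"M_c{i}_s{j}"]
            flank1 = (f"{g}_x1", "other", random_protein(100, rng), [])
            flank2 = (f"{g}_x2", "other", random_protein(100, rng), [])
            if i in fusion_clades:
                arch = "D"
                fused = l_seq + FUSION_LINKER + m_seq
                d1 = (1, len(l_seq))
                d2 = (len(l_seq) + len(FUSION_LINKER) + 1, len(fused))
                contig = lay.add_contig([
                    flank1,
                    (f"{g}_pufB", "pufB", accessory("pufB"), []),
                    (f"{g}_pufA", "pufA", accessory("pufA"), []),
                    (f"{g}_pufLM", "pufLM_fusion", fused, []),
                    (f"{g}_pufC", "pufC", accessory("pufC"), []),
                    flank2,
                ])
                truth_seqs[f"{g}_pufLM"] = SeqTruth("fusion", i, [d1, d2])
            else:
                arch = arch_assign[(i, j)]
                ldom = [(1, len(l_seq))]
                if arch == "A":
                    contig = lay.add_contig([
                        flank1,
                        (f"{g}_pufB", "pufB", accessory("pufB"), []),
                        (f"{g}_pufA", "pufA", accessory("pufA"), []),
                        (f"{g}_pufL", "pufL", l_seq, []),
                        (f"{g}_pufM", "pufM", m_seq, []),
                        (f"{g}_pufC", "pufC", accessory("pufC"), []),
                        flank2,
                    ])
                    mdom = SeqTruth("PufM", i, [(1, len(m_seq))])
                elif arch == "B":
                    contig = lay.add_contig([
                        flank1,
                        (f"{g}_pufL", "pufL", l_seq, []),
                        (f"{g}_pufM", "pufM", m_seq, []),
                        flank2,
                    ])
                    lay.add_contig([
                        (f"{g}_x3", "other", random_protein(100, rng), []),
                        (f"{g}_pufB", "pufB", accessory("pufB"), []),
                        (f"{g}_pufA", "pufA", accessory("pufA"), []),
                        (f"{g}_pufC", "pufC", accessory("pufC"), []),
                    ])
                    mdom = SeqTruth("PufM", i, [(1, len(m_seq))])
                elif arch == "C":
                    contig = lay.add_contig([
                        flank1,
                        (f"{g}_pufL", "pufL", l_seq, []),
                        (f"{g}_pufM", "pufM", m_seq, []),
                        flank2,
                        (f"{g}_x3", "other", random_protein(100, rng), []),
                    ])
                    mdom = SeqTruth("PufM", i, [(1, len(m_seq))])
                else:  # E: colocated operon with OmpA-like terminal fusions
                    m_fused = m_seq + ompa_instance()
                    c_core = accessory("pufC")
                    c_fused = ompa_instance() + c_core
                    contig = lay.add_contig([
                        flank1,
                        (f"{g}_pufB", "pufB", accessory("pufB"), []),
                        (f"{g}_pufA", "pufA", accessory("pufA"), []),
                        (f"{g}_pufL", "pufL", l_seq, []),
                        (f"{g}_pufM", "pufM", m_fused, ["OmpA_like:C_terminal"]),
                        (f"{g}_pufC", "pufC", c_fused, ["OmpA_like:N_terminal"]),
                        flank2,
                    ])
                    mdom = SeqTruth("PufM", i, [(1, len(m_seq))],
                                    ompa_domain=(len(m_seq) + 1, len(m_fused)))
                    truth_seqs[f"{g}_pufC"] = SeqTruth(
                        "accessory", -1, [],
                        ompa_domain=(1, len(c_fused) - len(c_core)))
                truth_seqs[f"{g}_pufL"] = SeqTruth("PufL", i, ldom)
                truth_seqs[f"{g}_pufM"] = mdom
            arch_truth[contig] = arch

    # leftover clades of the larger family: single-gene contigs
    for fam, n_clades, leaves, label in (
            ("PufL", config.n_clades_pufL, leaves_l, "pufL"),
            ("PufM", config.n_clades_pufM, leaves_m, "pufM")):
        for i in range(n_paired, n_clades):
            for j in range(config.seqs_per_clade):
                lay = new_layout(taxon_for_clade(i))
                g = lay.bin_id
                seq = leaves[f"{'L' if fam == 'PufL' else 'M'}_c{i}_s{j}"]
                lay.add_contig([(f"{g}_{label}", label, seq, [])])
                truth_seqs[f"{g}_{label}"] = SeqTruth(fam, i, [(1, len(seq))])

    # --- outgroup bins ---------------------------------------------------
    for cname, fam in (("OGA", "PsbA-like"), ("OGD", "PsbD-like")):
        lay = new_layout("Cyanobacteria")
        genes = []
        for j in range(config.n_outgroup_per_family):
            sid = f"{lay.bin_id}_psb{j}"
            seq = leaves_og[f"{cname}_s{j}"]
            genes.append((sid, "other", seq, []))
            truth_seqs[sid] = SeqTruth(fam, 0, [(1, len(seq))])
        lay.add_contig(genes)

    # --- divergent full-length homolog(s) --------------------------------
    for k in range(config.n_divergent):
        lay = new_layout("Chloroflexota")
        sid = f"{lay.bin_id}_div{k}"
        seq = mutate_sequence(l_root, config.divergent_extra_divergence, rng)
        lay.add_contig([(sid, "other", seq, [])])
        truth_seqs[sid] = SeqTruth("PufL", -1, [(1, len(seq))], divergent=True)

    # --- fragments --------------------------------------------------------
    family_ids = [sid for sid, t in truth_seqs.items()
                  if t.family in {"PufL", "PufM", "fusion"} and not t.divergent]
    n_frag = int(round(config.fragment_fraction * len(family_ids)))
    frag_ids = set(rng.choice(family_ids, size=n_frag, replace=False)) if n_frag else set()
    for lay in layouts:
        for k, p in enumerate(lay.proteins):
            if p.seq_id in frag_ids:
                frag, offset = _truncate_fragment(p.sequence, rng)
                t = truth_seqs[p.seq_id]
                t.fragment = True
                t.domains = _clip_domains(t.domains, offset, len(frag))
                lay.proteins[k] = dataclasses.replace(p, sequence=frag)
                for f in lay.features:
                    if f.gene_id == p.seq_id:
                        f.end = f.start + 3 * (len(frag) + 1) - 1

    # --- decoys and contaminant/filler bins ------------------------------
    all_family_seqs = [p.sequence for lay in layouts for p in lay.proteins
                       if truth_seqs.get(p.seq_id, SeqTruth("other")).family
                       in {"PufL", "PufM", "fusion"}]

    def decoy_seq() -> str:
        src = all_family_seqs[int(rng.integers(0, len(all_family_seqs)))]
        return "".join(rng.permutation(list(src)))

    decoy_layouts = []
    for _ in range(config.n_cold_bins + config.n_filler_bins):
        lay = new_layout("Unclassified")
        decoy_layouts.append(lay)
    # distribute decoys round-robin over the contaminant/filler bins
    for d in range(config.n_decoys):
        lay = decoy_layouts[d % len(decoy_layouts)] if decoy_layouts else new_layout("Unclassified")
        sid = f"{lay.bin_id}_decoy{d}"
        seq = decoy_seq()
        lay.add_contig([(sid, "other", seq, [])])
        truth_seqs[sid] = SeqTruth("decoy")
    cold_bin_ids = {lay.bin_id for lay in decoy_layouts[:config.n_cold_bins]}

    # --- bin metadata -----------------------------------------------------
    bins: list[BinInfo] = []
    for lay in layouts:
        if lay.bin_id in cold_bin_ids:
            t = float(rng.uniform(*config.temp_range_cold))
        else:
            t = float(rng.uniform(*config.temp_range_hot))
        bins.append(BinInfo(lay.bin_id, round(t, 1), HOT_SUBTYPE, lay.taxon))
    if decoy_layouts:  # one filler bin carries the wrong ecosystem label
        wrong = decoy_layouts[-1].bin_id
        for b in bins:
            if b.bin_id == wrong:
                b.ecosystem_subtype = WARM_SUBTYPE

    n_missing = int(round(config.missing_temp_fraction * len(bins)))
    # blank temperatures on bins without planted Puf signal first, so the
    # curation exercise does not silently delete the planted structure
    signal_bins = {lay.bin_id for lay in layouts
                   if any(truth_seqs.get(p.seq_id, SeqTruth("other")).family
                          != "decoy" for p in lay.proteins)}
    candidates = ([b for b in bins if b.bin_id not in signal_bins
                   and b.bin_id not in cold_bin_ids]
                  + [b for b in bins if b.bin_id in cold_bin_ids]
                  + [b for b in bins if b.bin_id in signal_bins])
    for b in candidates[:n_missing]:
        b.temperature_c = None

    hot_lo, hot_hi = config.temp_range_hot
    truth_bins = {b.bin_id: (b.temperature_c is not None
                             and hot_lo <= b.temperature_c <= hot_hi)
                  for b in bins}

    # --- seed alignments for profile building ----------------------------
    # the RC seed covers all four sub-families (L, M and the D1/D2 analogs),
    # as the real reaction-center Pfam family does
    rc_seed = []
    for fam, leaves, n_clades in (("L", leaves_l, config.n_clades_pufL),
                                  ("M", leaves_m, config.n_clades_pufM)):
        for i in range(n_clades):
            for j in range(min(2, config.seqs_per_clade)):
                lbl = f"{fam}_c{i}_s{j}"
                rc_seed.append(SeqRecordX(seq_id=f"seed_{lbl}", sequence=leaves[lbl]))
    for cname in ("OGA", "OGD"):
        for j in range(min(2, config.n_outgroup_per_family)):
            lbl = f"{cname}_s{j}"
            rc_seed.append(SeqRecordX(seq_id=f"seed_{lbl}", sequence=leaves_og[lbl]))
    ompa_seed = [SeqRecordX(seq_id=f"seed_ompa{k}", sequence=ompa_instance())
                 for k in range(6)]

    proteins = [p for lay in layouts for p in lay.proteins]
    features = [f for lay in layouts for f in lay.features]
    for p in proteins:
        p.hot_spring = truth_bins[p.bin_id]
        if p.seq_id not in truth_seqs:
            truth_seqs[p.seq_id] = SeqTruth(
                "accessory" if p.seq_id.rsplit("_", 1)[-1].startswith("puf") else "other")

    # --- synthetic reference database for uniqueness accounting ----------
    # Every RC family member outside the designated "novel" clades gets a
    # near-identical (~98 %) reference counterpart, as do the outgroup
    # families; fusion references cover the individual domains.  Members of
    # novel clades and the divergent homolog have no counterpart, so they
    # are the planted "unique" sequences.
    references: list[SeqRecordX] = []
    by_id = {p.seq_id: p for p in proteins}
    for sid in sorted(truth_seqs):
        t = truth_seqs[sid]
        if t.divergent or sid not in by_id:
            continue
        if t.family in {"PufL", "PufM"} and t.clade not in config.novel_clade_indices:
            references.append(SeqRecordX(
                seq_id=f"ref_{sid}",
                sequence=mutate_sequence(by_id[sid].sequence,
                                         config.reference_divergence, rng)))
        elif t.family == "fusion" and t.clade not in config.novel_clade_indices:
            for k, (s, e) in enumerate(t.domains):
                references.append(SeqRecordX(
                    seq_id=f"ref_{sid}_d{k}",
                    sequence=mutate_sequence(by_id[sid].sequence[s - 1:e],
                                             config.reference_divergence, rng)))
        elif t.family in {"PsbA-like", "PsbD-like"}:
            references.append(SeqRecordX(
                seq_id=f"ref_{sid}",
                sequence=mutate_sequence(by_id[sid].sequence,
                                         config.reference_divergence, rng)))

    outgroup_members = sorted(sid for sid, t in truth_seqs.items()
                              if t.family in {"PsbA-like", "PsbD-like"})
    psba = [s for s in outgroup_members if truth_seqs[s].family == "PsbA-like"]
    psbd = [s for s in outgroup_members if truth_seqs[s].family == "PsbD-like"]
    outgroup_refs = psba[:2] + psbd[:1]

    dataset = SyntheticDataset(
        config=config, bins=bins, proteins=proteins, features=features,
        truth=TruthTable(truth_seqs, truth_bins, arch_truth),
        rc_seed=rc_seed, ompa_seed=ompa_seed,
        references=references, outgroup_refs=outgroup_refs)
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# on-disk round trip (FASTA + TSV + GFF3 + JSON)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write per-bin protein FASTA, bin metadata TSV, GFF3 features and the
    truth/config JSON.  Round-trips losslessly through :func:`read_dataset`."""
    from . import io as pio
    out = Path(out_dir)
    (out / "proteins").mkdir(parents=True, exist_ok=True)
    for b in dataset.bins:
        pio.write_fasta(dataset.proteins_in_bin(b.bin_id),
                        out / "proteins" / f"{b.bin_id}.faa")
    pio.write_bin_metadata(dataset.bins, out / "bins.tsv")
    pio.write_gff3(dataset.features, out / "features.gff3")
    pio.write_fasta(dataset.rc_seed, out / "rc_seed.faa")
    pio.write_fasta(dataset.ompa_seed, out / "ompa_seed.faa")
    pio.write_fasta(dataset.references, out / "references.faa")
    truth_doc = {
        "config": {k: (sorted(v) if isinstance(v, frozenset) else
                       list(map(list, v)) if k == "architecture_mix" else
                       list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(dataset.config).items()},
        "sequences": {sid: {
            "family": t.family, "clade": t.clade,
            "domains": [list(d) for d in t.domains],
            "ompa_domain": list(t.ompa_domain) if t.ompa_domain else None,
            "fragment": t.fragment, "divergent": t.divergent,
        } for sid, t in sorted(dataset.truth.sequences.items())},
        "bins": dataset.truth.bins,
        "contigs": dataset.truth.contigs,
        "outgroup_refs": dataset.outgroup_refs,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1, sort_keys=True))


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Inverse of :func:`write_dataset`."""
    from . import io as pio
    src = Path(in_dir)
    doc = json.loads((src / "truth.json").read_text())
    cfg = dict(doc["config"])
    cfg["fusion_clade_indices"] = frozenset(cfg["fusion_clade_indices"])
    cfg["novel_clade_indices"] = frozenset(cfg["novel_clade_indices"])
    cfg["architecture_mix"] = tuple((c, w) for c, w in cfg["architecture_mix"])
    cfg["temp_range_hot"] = tuple(cfg["temp_range_hot"])
    cfg["temp_range_cold"] = tuple(cfg["temp_range_cold"])
    config = SimConfig(**cfg)
    bins = pio.read_bin_metadata(src / "bins.tsv")
    features = pio.read_gff3(src / "features.gff3")
    truth_bins = doc["bins"]
    proteins = []
    for b in bins:
        for rec in pio.read_fasta(src / "proteins" / f"{b.bin_id}.faa"):
            rec.bin_id = b.bin_id
            rec.taxon = b.taxon
            rec.hot_spring = truth_bins[b.bin_id]
            proteins.append(rec)
    truth_seqs = {sid: SeqTruth(
        family=t["family"], clade=t["clade"],
        domains=[tuple(d) for d in t["domains"]],
        ompa_domain=tuple(t["ompa_domain"]) if t["ompa_domain"] else None,
        fragment=t["fragment"], divergent=t["divergent"],
    ) for sid, t in doc["sequences"].items()}
    return SyntheticDataset(
        config=config, bins=bins, proteins=proteins, features=features,
        truth=TruthTable(truth_seqs, truth_bins, doc["contigs"]),
        rc_seed=pio.read_fasta(src / "rc_seed.faa"),
        ompa_seed=pio.read_fasta(src / "ompa_seed.faa"),
        references=pio.read_fasta(src / "references.faa"),
        outgroup_refs=doc["outgroup_refs"])
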