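"""Sequence similarity networks.

Sequences are first collapsed into representative nodes at 95 % identity
(greedy, longest-first, CD-HIT style); every unordered pair of
representatives is then scored by local alignment, and edges are kept where
the alignment score (AS = -log10 E) reaches the chosen threshold.  Connected
components are the network's clusters; edgeless nodes are flagged as
singletons and, by default, excluded from downstream analysis (they are
typically fragments — but see the rescue scan for the one pitfall this
policy has).

The E-value search space m·n is fixed per network build (mean representative
length × total representative length), so AS values are symmetric and
reproducible across runs and thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .align import global_align, local_align, percent_identity
from .records import SeqRecordX

DEFAULT_ID_THRESHOLD = 0.95


@dataclass
class SSNNode:
    node_id: str
    representative: SeqRecordX
    member_seq_ids: list
    taxon: str | None = None
    hot_spring: bool = False
    domain_kind: str = "unassigned"

    @property
    def representative_seq_id(self) -> str:
        return self.representative.seq_id


@dataclass
class SSN:
    nodes: list                      # of SSNNode
    edges: list                      # of (node_id, node_id, AS) with id1 < id2
    threshold: float
    clusters: dict = field(default_factory=dict)   # node_id -> cluster label

    def node(self, node_id: str) -> SSNNode:
        return next(n for n in self.nodes if n.node_id == node_id)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.node_id, representative=n.representative_seq_id,
                       taxon=n.taxon or "", hot_spring=bool(n.hot_spring),
                       domain_kind=n.domain_kind,
                       cluster=str(self.clusters.get(n.node_id, "")))
        for a, b, s in self.edges:
            g.add_edge(a, b, alignment_score=float(s))
        return g


def _identity(a: str, b: str) -> float:
    return percent_identity(global_align(a, b), "shorter_sequence")


def collapse_identical(seqs: list[SeqRecordX],
                       id_threshold: float = DEFAULT_ID_THRESHOLD,
                       identity_mode: str = "shorter_sequence") -> list[SSNNode]:
    """Greedy incremental clustering into representative nodes.

    Sequences are processed by decreasing length (ties broken by id); each
    joins the first existing node whose representative reaches the identity
    threshold (identity over the shorter sequence by default), else founds a
    new node.  Because processing is longest-first, the representative is
    always a longest member of its node.
    """
    ordered = sorted(seqs, key=lambda r: (-len(r.sequence), r.seq_id))
    nodes: list[SSNNode] = []
    for rec in ordered:
        joined = False
        for node in nodes:
            ident = percent_identity(
                global_align(rec.sequence, node.representative.sequence),
                identity_mode)
            if ident >= id_threshold:
                node.member_seq_ids.append(rec.seq_id)
                joined = True
                break
        if not joined:
            nodes.append(SSNNode(
                node_id=f"node_{len(nodes):04d}",
                representative=rec,
                member_seq_ids=[rec.seq_id],
                taxon=rec.taxon,
                hot_spring=bool(rec.hot_spring),
                domain_kind=_infer_domain_kind(rec)))
    return nodes


def _infer_domain_kind(rec: SeqRecordX) -> str:
    if rec.seq_id.startswith("N_"):
        return "N_domain"
    if rec.seq_id.startswith("C_"):
        return "C_domain"
    return "unassigned"


def all_vs_all_scores(nodes: list[SSNNode]) -> pd.DataFrame:
    """Local-alignment AS for every unordered representative pair."""
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes for an all-vs-all table")
    lengths = [len(n.representative.sequence) for n in nodes]
    mn = int(round(sum(lengths) / len(lengths))) * sum(lengths)
    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            res = local_align(a.representative.sequence,
                              b.representative.sequence, mn=mn)
            rows.append((a.node_id, b.node_id, res.alignment_score))
    return pd.DataFrame(rows, columns=["node1", "node2", "alignment_score"])


def build_ssn(nodes: list[SSNNode], edge_table: pd.DataFrame,
              as_threshold: float) -> SSN:
    """Threshold the edge table and label connected components."""
    kept = edge_table[edge_table["alignment_score"] >= as_threshold]
    edges = [(min(a, b), max(a, b), float(s))
             for a, b, s in kept.itertuples(index=False)]
    ssn = SSN(nodes=nodes, edges=sorted(edges), threshold=as_threshold)
    ssn.clusters = components_and_clusters(ssn)
    return ssn


def components_and_clusters(ssn: SSN, drop_singletons: bool = True) -> dict:
    """Label connected components ``1..k`` by decreasing size (ties by
    smallest node id); edgeless nodes are labeled ``"singleton"``."""
    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in ssn.nodes)
    g.add_edges_from((a, b) for a, b, _ in ssn.edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    real = sorted([c for c in comps if len(c) > 1], key=lambda c: (-len(c), c[0]))
    labels: dict[str, str] = {}
    for k, comp in enumerate(real, start=1):
        for node_id in comp:
            labels[node_id] = str(k)
    for comp in comps:
        if len(comp) == 1:
            labels[comp[0]] = "singleton"
    return labels


def nonsingleton_nodes(ssn: SSN) -> list:
    return [n for n in ssn.nodes if ssn.clusters.get(n.node_id) != "singleton"]


def cluster_composition(ssn: SSN) -> pd.DataFrame:
    """Per-cluster percent of nodes by taxon class, plus percent hot-spring.

    Taxon percentages within a cluster sum to 100 (up to rounding)."""
    rows = []
    by_cluster: dict[str, list] = {}
    for n in ssn.nodes:
        label = ssn.clusters.get(n.node_id, "singleton")
        if label == "singleton":
            continue
        by_cluster.setdefault(label, []).append(n)
    for label in sorted(by_cluster, key=lambda x: (len(x), x)):
        members = by_cluster[label]
        taxa = pd.Series([m.taxon or "Unclassified" for m in members])
        pct = taxa.value_counts(normalize=True) * 100
        hot = 100.0 * sum(bool(m.hot_spring) for m in members) / len(members)
        for taxon, p in pct.items():
            rows.append({"cluster": label, "taxon": taxon,
                         "percent_nodes": round(float(p), 1),
                         "percent_hot_spring": round(hot, 1),
                         "n_nodes": len(members)})
    return pd.DataFrame(rows, columns=["cluster", "taxon", "percent_nodes",
                                       "percent_hot_spring", "n_nodes"])


# ---------------------------------------------------------------------------
# export / import


def export_network(ssn: SSN, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network with node attributes; ``graphml``, ``xgmml`` or
    ``tsv`` (edge list plus a ``<stem>.nodes.tsv`` attribute table)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(ssn.graph(), path)
    elif fmt == "xgmml":
        _write_xgmml(ssn, path)
    elif fmt == "tsv":
        pd.DataFrame(ssn.edges, columns=["node1", "node2", "alignment_score"]
                     ).to_csv(path, sep="\t", index=False)
        _node_frame(ssn).to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


_NODE_COLUMNS = ["node_id", "representative", "members", "taxon",
                 "hot_spring", "domain_kind", "cluster"]


def _node_frame(ssn: SSN) -> pd.DataFrame:
    return pd.DataFrame([{
        "node_id": n.node_id,
        "representative": n.representative_seq_id,
        "members": ",".join(n.member_seq_ids),
        "taxon": n.taxon or "",
        "hot_spring": bool(n.hot_spring),
        "domain_kind": n.domain_kind,
        "cluster": ssn.clusters.get(n.node_id, ""),
    } for n in ssn.nodes], columns=_NODE_COLUMNS)


def _write_xgmml(ssn: SSN, path: Path) -> None:
    from lxml import etree
    root = etree.Element("graph", label="pufminer SSN",
                         nsmap={None: "http://www.cs.rpi.edu/XGMML"})
    root.set("directed", "0")
    for n in ssn.nodes:
        el = etree.SubElement(root, "node", id=n.node_id, label=n.node_id)
        for key, val in (("representative", n.representative_seq_id),
                         ("taxon", n.taxon or ""),
                         ("hot_spring", str(bool(n.hot_spring))),
                         ("domain_kind", n.domain_kind),
                         ("cluster", str(ssn.clusters.get(n.node_id, "")))):
            etree.SubElement(el, "att", name=key, value=val, type="string")
    for a, b, s in ssn.edges:
        el = etree.SubElement(root, "edge", source=a, target=b,
                              label=f"{a}-{b}")
        etree.SubElement(el, "att", name="alignment_score",
                         value=repr(float(s)), type="real")
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Load an exported network back as a networkx graph (attributes kept)."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "xgmml":
        from lxml import etree
        tree = etree.parse(str(path))
        ns = {"x": "http://www.cs.rpi.edu/XGMML"}
        g = nx.Graph()
        for el in tree.findall("x:node", ns):
            attrs = {a.get("name"): a.get("value") for a in el.findall("x:att", ns)}
            g.add_node(el.get("id"), **attrs)
        for el in tree.findall("x:edge", ns):
            attrs = {a.get("name"): float(a.get("value"))
                     for a in el.findall("x:att", ns)}
            g.add_edge(el.get("source"), el.get("target"), **attrs)
        return g
    if fmt == "tsv":
        g = nx.Graph()
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t",
                            keep_default_na=False)
        for _, row in nodes.iterrows():
            g.add_node(row["node_id"], **{k: row[k] for k in nodes.columns
                                          if k != "node_id"})
        edges = pd.read_csv(path, sep="\t")
        for _, row in edges.iterrows():
            g.add_edge(row["node1"], row["node2"],
                       alignment_score=float(row["alignment_score"]))
        return g
    raise ValueError(f"unknown network format {fmt!r}")
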