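"""Alignment editing, redundancy reduction and distance-based phylogeny.

The tree stage mirrors a standard protein workflow: progressive multiple
alignment over a k-mer-distance guide tree, removal of fragments and gappy
columns, redundancy reduction at 95 % identity between aligned positions
(discarding the shorter sequence of each redundant pair, iterated to a fixed
point), neighbor-joining on p-distances (optionally Poisson-corrected), and
outgroup rooting.  Neighbor joining is exact on additive distance matrices,
which is what the planted-clade recovery tests rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._dp import affine_dp
from .align import default_matrix
from .records import SeqRecordX
from .simulate import AA, _AA_INDEX

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class MSA:
    """A multiple sequence alignment with an edit log."""

    ids: list
    rows: dict                      # id -> gapped sequence
    log: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped_length(self, seq_id: str) -> int:
        return sum(1 for c in self.rows[seq_id] if c != GAP)

    def validate(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if set(self.ids) != set(self.rows):
            raise ValueError("ids and rows disagree")


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_columns(rows: list[str]) -> np.ndarray:
    """(n_cols, 20) residue frequencies, gaps excluded from the numerator
    but counted in the denominator (gap positions score 0)."""
    ncol = len(rows[0])
    freq = np.zeros((ncol, 20))
    for row in rows:
        for j, c in enumerate(row):
            idx = _AA_INDEX.get(c)
            if idx is not None:
                freq[j, idx] += 1
    return freq / len(rows)


_BLOSUM_DENSE = None


def _blosum_dense() -> np.ndarray:
    global _BLOSUM_DENSE
    if _BLOSUM_DENSE is None:
        m = default_matrix()
        _BLOSUM_DENSE = np.array([[m[a][b] for b in AA] for a in AA], dtype=float)
    return _BLOSUM_DENSE


def _merge_groups(rows_a: list[str], rows_b: list[str],
                  gap_open: float = 11.0, gap_extend: float = 1.0):
    fa = _profile_columns(rows_a)
    fb = _profile_columns(rows_b)
    S = fa @ _blosum_dense() @ fb.T
    _, path = affine_dp(S, gap_open, gap_extend, "global")
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for pi, pj in path:
        for k, row in enumerate(rows_a):
            out_a[k] += row[pi] if pi is not None else GAP
        for k, row in enumerate(rows_b):
            out_b[k] += row[pj] if pj is not None else GAP
    return out_a, out_b


def build_msa(seqs: list[SeqRecordX], k: int = 3,
              gap_open: float = 11.0, gap_extend: float = 1.0) -> MSA:
    """Progressive alignment over an average-linkage k-mer-distance guide
    tree; pairwise and profile–profile steps use BLOSUM62 affine-gap DP.
    Deterministic for a fixed input order."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = [r.seq_id for r in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment input")
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[i].sequence, seqs[j].sequence, k)
    link = hierarchy.linkage(squareform(dm, checks=False), method="average")
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i].sequence]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(link):
        ids_a, rows_a = groups.pop(int(a))
        ids_b, rows_b = groups.pop(int(b))
        new_a, new_b = _merge_groups(rows_a, rows_b, gap_open, gap_extend)
        groups[n + step] = (ids_a + ids_b, new_a + new_b)
    final_ids, final_rows = groups.popitem()[1]
    msa = MSA(ids=list(ids), rows={i: r for i, r in zip(final_ids, final_rows)})
    msa.validate()
    return msa


# ---------------------------------------------------------------------------
# alignment editing


def edit_msa(msa: MSA, min_row_coverage: float = 0.6,
             max_col_gap_fraction: float = 0.5) -> MSA:
    """Automated stand-in for manual alignment editing: drop fragment rows
    (non-gap coverage below ``min_row_coverage`` of the median ungapped
    length), then drop columns whose gap fraction exceeds
    ``max_col_gap_fraction``.  Every removal is logged."""
    msa.validate()
    lengths = {i: msa.ungapped_length(i) for i in msa.ids}
    median = float(np.median(list(lengths.values())))
    edit_log = list(msa.log)
    kept_ids = []
    for i in msa.ids:
        if lengths[i] < min_row_coverage * median:
            edit_log.append(f"removed row {i}: coverage {lengths[i]}/"
                            f"{median:.0f} below {min_row_coverage}")
        else:
            kept_ids.append(i)
    if not kept_ids:
        raise ValueError("alignment editing removed every row")
    rows = {i: msa.rows[i] for i in kept_ids}
    ncol = len(next(iter(rows.values())))
    keep_cols = []
    for j in range(ncol):
        gap_fraction = sum(1 for i in kept_ids if rows[i][j] == GAP) / len(kept_ids)
        if gap_fraction > max_col_gap_fraction:
            edit_log.append(f"removed column {j + 1}: gap fraction "
                            f"{gap_fraction:.2f} above {max_col_gap_fraction}")
        else:
            keep_cols.append(j)
    if not keep_cols:
        raise ValueError("alignment editing removed every column")
    new_rows = {i: "".join(rows[i][j] for j in keep_cols) for i in kept_ids}
    return MSA(ids=kept_ids, rows=new_rows, log=edit_log)


def aligned_identity(row_a: str, row_b: str) -> float:
    """Identity between the aligned positions (columns where both rows have
    a residue) of two rows of one alignment."""
    both = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def remove_redundant(msa: MSA, threshold: float = 0.95) -> MSA:
    """Discard the shorter sequence of any pair whose aligned-positions
    identity exceeds ``threshold`` (ties broken against the
    lexicographically later id); scanned in row order, iterated to a fixed
    point."""
    ids = list(msa.ids)
    edit_log = list(msa.log)
    changed = True
    while changed:
        changed = False
        for i_pos in range(len(ids)):
            if changed:
                break
            for j_pos in range(i_pos + 1, len(ids)):
                a, b = ids[i_pos], ids[j_pos]
                ident = aligned_identity(msa.rows[a], msa.rows[b])
                if ident > threshold:
                    la = msa.ungapped_length(a)
                    lb = msa.ungapped_length(b)
                    if la < lb or (la == lb and a > b):
                        drop = a
                    else:
                        drop = b
                    ids.remove(drop)
                    edit_log.append(
                        f"removed redundant row {drop}: {ident:.3f} identity "
                        f"to {a if drop == b else b}")
                    changed = True
                    break
    return MSA(ids=ids, rows={i: msa.rows[i] for i in ids}, log=edit_log)


# ---------------------------------------------------------------------------
# distances and neighbor joining


def distance_matrix(msa: MSA, distance: str = "p_distance") -> pd.DataFrame:
    """Pairwise distances over aligned positions; ``poisson_corrected``
    applies -ln(1 - p).  A pair with no overlapping positions is an error
    naming the pair."""
    ids = list(msa.ids)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = msa.rows[ids[i]], msa.rows[ids[j]]
            both = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
            if not both:
                raise ValueError(f"no overlapping aligned positions between "
                                 f"{ids[i]} and {ids[j]}")
            p = sum(1 for x, y in both if x != y) / len(both)
            if distance == "p_distance":
                val = p
            elif distance == "poisson_corrected":
                if p >= 1.0:
                    raise ValueError(f"saturated distance between {ids[i]} "
                                     f"and {ids[j]}")
                val = -np.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance {distance!r}")
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_tree(dm_or_msa, distance: str = "p_distance") -> dendropy.Tree:
    """Standard neighbor joining; accepts an :class:`MSA` or a precomputed
    distance DataFrame.  Deterministic: ties in the Q criterion are broken
    by id order.  Returns an unrooted dendropy tree."""
    if isinstance(dm_or_msa, MSA):
        dm = distance_matrix(dm_or_msa, distance)
    else:
        dm = dm_or_msa
    ids = list(dm.index)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {}
    for label in ids:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=label)
        nodes[label] = node
    D = {a: {b: float(dm.loc[a, b]) for b in ids} for a in ids}
    active = list(ids)
    counter = 0
    while len(active) > 3:
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (len(active) - 2) * D[a][b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        dab = D[a][b]
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (len(active) - 2))
        vb = dab - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        new_label = f"_nj{counter}"
        counter += 1
        parent = dendropy.Node()
        child_a, child_b = nodes[a], nodes[b]
        child_a.edge.length = va
        child_b.edge.length = vb
        parent.add_child(child_a)
        parent.add_child(child_b)
        nodes[new_label] = parent
        D[new_label] = {}
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (D[a][c] + D[b][c] - dab)
            D[new_label][c] = dn
            D[c][new_label] = dn
        active = [c for c in active if c not in (a, b)] + [new_label]
    # join the last three nodes at the (unrooted) central vertex
    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    for label, length in ((a, la), (b, lb), (c, lc)):
        node = nodes[label]
        node.edge.length = max(length, 0.0)
        tree.seed_node.add_child(node)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# rooting and annotation


def leaf_labels(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def root_at_outgroup(tree: dendropy.Tree, outgroup_ids) -> dendropy.Tree:
    """Root on the branch that best separates the outgroup from the ingroup.

    If the outgroup is monophyletic in the unrooted tree this is the branch
    above its most recent common ancestor; otherwise the edge maximizing
    outgroup purity is used and a warning is logged."""
    outgroup = set(outgroup_ids)
    tree = tree.clone(depth=1)
    present = set(leaf_labels(tree)) & outgroup
    if not present:
        raise ValueError("no outgroup id present in the tree")
    all_leaves = set(leaf_labels(tree))
    best = None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        for side in (below, all_leaves - below):
            if not side or side == all_leaves:
                continue
            misplaced = len(side - outgroup) + len((all_leaves - side) & outgroup)
            key = (misplaced, -len(side & outgroup), tuple(sorted(side))[:1])
            if best is None or key < best[0]:
                best = (key, edge, side)
    (misplaced, _, _), edge, _ = best
    if misplaced > 0:
        log.warning("outgroup not monophyletic: %d leaves misplaced at the "
                    "best rooting edge", misplaced)
    half = (edge.length or 0.0) / 2
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


def is_monophyletic(tree: dendropy.Tree, leaf_ids) -> bool:
    """True if ``leaf_ids`` form a clade in the (rooted) tree."""
    target = set(leaf_ids)
    mrca = tree.mrca(taxon_labels=sorted(target))
    if mrca is None:
        return False
    below = {lf.taxon.label for lf in mrca.leaf_iter()}
    return below == target


def annotate_tree(tree: dendropy.Tree, metadata: dict) -> tuple[pd.DataFrame, str, str]:
    """Per-leaf annotation table + Newick + an iTOL-style color-strip text.

    ``metadata`` maps leaf id to a dict with any of: cluster, phylum, hot,
    unique, fragment.  Missing leaves get blank fields and a warning."""
    rows = []
    for label in leaf_labels(tree):
        meta = metadata.get(label)
        if meta is None:
            log.warning("no annotation metadata for leaf %s", label)
            meta = {}
        rows.append({
            "leaf": label,
            "cluster": str(meta.get("cluster", "")),
            "phylum": str(meta.get("phylum", "")),
            "hot_spring": bool(meta.get("hot", False)),
            "unique": bool(meta.get("unique", False)),
            "fragment": bool(meta.get("fragment", False)),
        })
    table = pd.DataFrame(rows, columns=["leaf", "cluster", "phylum",
                                        "hot_spring", "unique", "fragment"])
    newick = tree.as_string(schema="newick").strip()
    itol = ["DATASET_BINARY", "SEPARATOR TAB", "DATASET_LABEL\tpufminer",
            "FIELD_SHAPES\t2\t2\t2", "FIELD_LABELS\thot\tunique\tfragment",
            "DATA"]
    for row in rows:
        itol.append("\t".join([row["leaf"],
                               "1" if row["hot_spring"] else "0",
                               "1" if row["unique"] else "0",
                               "1" if row["fragment"] else "0"]))
    return table, newick, "\n".join(itol)
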