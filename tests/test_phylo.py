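"""Alignment editing, redundancy, neighbor joining, rooting, annotation."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from pufminer.phylo import (MSA, aligned_identity, annotate_tree, build_msa,
                            distance_matrix, edit_msa, is_monophyletic,
                            leaf_labels, nj_tree, remove_redundant,
                            root_at_outgroup)
from pufminer.records import SeqRecordX
from pufminer.simulate import random_protein

from oracles import replay_redundancy


def recs(pairs):
    return [SeqRecordX(i, s) for i, s in pairs]


class TestBuildMSA:
    def test_identical_pair_aligns_gapless(self):
        msa = build_msa(recs([("a", "MKVLWAALEG"), ("b", "MKVLWAALEG")]))
        assert msa.n_columns == 10
        assert "-" not in msa.rows["a"] + msa.rows["b"]

    def test_no_indel_families_align_gapless(self, dataset):
        seqs = [dataset.seq(s) for s, t in dataset.truth.sequences.items()
                if t.family == "PufL" and t.clade == 0][:5]
        msa = build_msa(seqs)
        assert all("-" not in row for row in msa.rows.values())

    def test_guide_tree_not_worse_than_reversed_input_order(self):
        """Sum-of-pairs identity under the guide tree is at least that of a
        naive reversed-order progressive join on a toy set with indels."""
        rng = np.random.default_rng(8)
        core = random_protein(40, rng)
        seqs = [("a", core), ("b", core[:20] + core[25:]),
                ("c", core[:10] + "W" + core[10:]), ("d", core[5:])]

        def sum_pairs(msa):
            return sum(aligned_identity(msa.rows[x], msa.rows[y])
                       for x, y in itertools.combinations(msa.ids, 2))

        good = build_msa(recs(seqs))
        poor = build_msa(recs(list(reversed(seqs))))
        assert sum_pairs(good) >= sum_pairs(poor) - 1e-9

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            build_msa(recs([("a", "MKVL")]))


class TestEditMSA:
    def test_clean_alignment_unchanged(self):
        msa = MSA(ids=["a", "b"], rows={"a": "MKVL", "b": "MKVI"})
        out = edit_msa(msa)
        assert out.rows == msa.rows

    def test_planted_fragment_removed(self, dataset):
        frag_ids = {s for s, t in dataset.truth.sequences.items()
                    if t.fragment and t.family == "PufL"}
        full_ids = [s for s, t in dataset.truth.sequences.items()
                    if t.family == "PufL" and not t.fragment][:6]
        assert frag_ids
        some_frag = sorted(frag_ids)[0]
        msa = build_msa([dataset.seq(s) for s in full_ids + [some_frag]])
        out = edit_msa(msa)
        assert some_frag not in out.ids
        assert any(some_frag in entry for entry in out.log)

    def test_all_gap_column_removed(self):
        msa = MSA(ids=["a", "b", "c"],
                  rows={"a": "MK-L", "b": "MK-L", "c": "MK-I"})
        out = edit_msa(msa)
        assert out.n_columns == 3
        assert out.rows["a"] == "MKL"

    def test_error_when_everything_removed(self):
        msa = MSA(ids=["a", "b"], rows={"a": "----", "b": "----"})
        with pytest.raises(ValueError):
            edit_msa(msa)


class TestRemoveRedundant:
    def test_shorter_of_redundant_pair_discarded(self):
        """Two rows above 95% aligned identity with ungapped lengths 300 vs
        250: the 250-residue row goes."""
        rng = np.random.default_rng(2)
        long = random_protein(300, rng)
        short = long[:250]
        msa = MSA(ids=["long", "short"],
                  rows={"long": long, "short": short + "-" * 50})
        out = remove_redundant(msa)
        assert out.ids == ["long"]

    def test_no_pair_above_threshold_unchanged(self, dataset):
        seqs = [dataset.seq(s) for s, t in dataset.truth.sequences.items()
                if t.family == "PufM" and not t.fragment][:5]
        msa = build_msa(seqs)
        out = remove_redundant(msa)
        assert out.ids == msa.ids

    def test_matches_exhaustive_replay_on_toy_alignments(self):
        """Six-row toy alignments: survivors equal an independent replay of
        the published rule (shorter discarded, row-order scan, fixpoint)."""
        rng = np.random.default_rng(9)
        for trial in range(5):
            base = random_protein(60, rng)
            rows = {}
            for k in range(6):
                cut = rng.integers(0, 12)
                seq = list(base)
                for _ in range(rng.integers(0, 4)):
                    pos = int(rng.integers(0, 60))
                    seq[pos] = "W"
                row = "".join(seq)
                if cut:
                    row = row[:-cut] + "-" * int(cut)
                rows[f"r{k}"] = row
            msa = MSA(ids=list(rows), rows=dict(rows))
            out = remove_redundant(msa)
            assert out.ids == replay_redundancy(rows), rows

    def test_survivors_all_below_threshold(self, pipeline):
        msa_ids_seen = set()
        rng = np.random.default_rng(4)
        base = random_protein(80, rng)
        rows = {f"s{k}": base[:k] + "W" * 2 + base[k + 2:] for k in range(6)}
        out = remove_redundant(MSA(ids=list(rows), rows=rows))
        for x, y in itertools.combinations(out.ids, 2):
            assert aligned_identity(out.rows[x], out.rows[y]) <= 0.95


class TestNJ:
    def test_three_taxa_closed_form(self):
        ids = list("ABC")
        dm = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                          index=ids, columns=ids, dtype=float)
        tree = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.5 * (5 + 9 - 10))
        assert lengths["B"] == pytest.approx(0.5 * (5 + 10 - 9))
        assert lengths["C"] == pytest.approx(0.5 * (9 + 10 - 5))

    @pytest.mark.parametrize("branches", [
        {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0, "internal": 3.0},
        {"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.5, "internal": 2.0},
    ])
    def test_exact_on_additive_four_taxon_matrices(self, branches):
        """NJ recovers the generating topology and branch lengths exactly
        from an additive matrix."""
        b = branches
        ids = list("ABCD")
        path = {
            ("A", "B"): b["A"] + b["B"],
            ("A", "C"): b["A"] + b["internal"] + b["C"],
            ("A", "D"): b["A"] + b["internal"] + b["D"],
            ("B", "C"): b["B"] + b["internal"] + b["C"],
            ("B", "D"): b["B"] + b["internal"] + b["D"],
            ("C", "D"): b["C"] + b["D"],
        }
        dm = pd.DataFrame(0.0, index=ids, columns=ids)
        for (x, y), d in path.items():
            dm.loc[x, y] = dm.loc[y, x] = d
        tree = nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (x, y), d in path.items():
            assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(d)
        rooted = root_at_outgroup(tree, ["C", "D"])
        assert is_monophyletic(rooted, ["A", "B"])

    def test_exact_on_additive_five_taxon_matrix(self):
        """Caterpillar five-taxon tree: all pairwise path lengths recovered."""
        tree_src = dendropy.Tree.get(
            data="((A:1,B:2):1,(C:1.5,(D:2,E:1):0.5):1);", schema="newick")
        pdm_src = tree_src.phylogenetic_distance_matrix()
        ids = ["A", "B", "C", "D", "E"]
        taxa_src = {t.label: t for t in tree_src.taxon_namespace}
        dm = pd.DataFrame(0.0, index=ids, columns=ids)
        for x, y in itertools.combinations(ids, 2):
            d = pdm_src.distance(taxa_src[x], taxa_src[y])
            dm.loc[x, y] = dm.loc[y, x] = d
        tree = nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for x, y in itertools.combinations(ids, 2):
            assert pdm.distance(taxa[x], taxa[y]) \
                == pytest.approx(dm.loc[x, y])

    def test_disjoint_rows_raise_naming_the_pair(self):
        msa = MSA(ids=["a", "b", "c"],
                  rows={"a": "MK--", "b": "--VL", "c": "MKVL"})
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            distance_matrix(msa)

    def test_needs_three_taxa(self):
        dm = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"],
                          columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestRooting:
    def _tree(self):
        ids = list("ABCD")
        dm = pd.DataFrame([[0, 2, 8, 8], [2, 0, 8, 8],
                           [8, 8, 0, 2], [8, 8, 2, 0]],
                          index=ids, columns=ids, dtype=float)
        return nj_tree(dm)

    def test_single_leaf_outgroup_roots_on_pendant_branch(self):
        rooted = root_at_outgroup(self._tree(), ["D"])
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [{lf.taxon.label for lf in c.leaf_iter()} for c in children]
        assert {"D"} in sides

    def test_missing_outgroup_is_an_error(self):
        with pytest.raises(ValueError):
            root_at_outgroup(self._tree(), ["Z"])

    def test_ingroup_clades_unchanged_by_rooting(self):
        rooted = root_at_outgroup(self._tree(), ["C", "D"])
        assert is_monophyletic(rooted, ["A", "B"])
        assert is_monophyletic(rooted, ["C", "D"])

    def test_simulated_outgroup_monophyletic_after_rooting(self, pipeline,
                                                           dataset):
        tree = pipeline.tree
        assert tree is not None
        outgroup_in_tree = [l for l in leaf_labels(tree)
                            if l in set(dataset.outgroup_refs)]
        assert outgroup_in_tree
        assert is_monophyletic(tree, outgroup_in_tree)


class TestAnnotation:
    def test_all_leaves_annotated_exactly_once(self, pipeline):
        tree = pipeline.tree
        table, newick, itol = annotate_tree(tree, {})
        assert sorted(table["leaf"]) == sorted(leaf_labels(tree))
        assert table["leaf"].is_unique

    def test_newick_round_trips_to_isomorphic_tree(self, pipeline):
        _, newick, _ = annotate_tree(pipeline.tree, {})
        back = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(l.taxon.label for l in back.leaf_node_iter()) \
            == sorted(leaf_labels(pipeline.tree))
        src = pipeline.tree.clone(depth=1)
        back.migrate_taxon_namespace(src.taxon_namespace)
        assert dendropy.calculate.treecompare.symmetric_difference(
            src, back, is_bipartitions_updated=False) == 0

    def test_metadata_passed_through(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        table, _, itol = annotate_tree(
            tree, {"A": {"cluster": "1", "hot": True, "unique": True}})
        row = table.set_index("leaf").loc["A"]
        assert row["cluster"] == "1" and row["hot_spring"] and row["unique"]
        assert "A\t1\t1\t0" in itol
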