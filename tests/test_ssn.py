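"""Similarity networks: collapsing, thresholding, clusters, exports."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pufminer.align import global_align, percent_identity
from pufminer.records import SeqRecordX
from pufminer.simulate import random_protein
from pufminer.ssn import (all_vs_all_scores, build_ssn, cluster_composition,
                          collapse_identical, components_and_clusters,
                          export_network, nonsingleton_nodes, read_network)

from conftest import true_group


def recs(seqs):
    return [SeqRecordX(f"q{i}", s) for i, s in enumerate(seqs)]


@pytest.fixture(scope="module")
def toy_nodes():
    rng = np.random.default_rng(5)
    base = random_protein(120, rng)
    near = base[:60] + "W" + base[61:]          # ~99% identical
    far = random_protein(120, rng)
    return collapse_identical(recs([base, near, far, far]))


class TestCollapseIdentical:
    def test_duplicates_form_one_node(self):
        rng = np.random.default_rng(0)
        seq = random_protein(100, rng)
        nodes = collapse_identical(recs([seq, seq]))
        assert len(nodes) == 1
        assert len(nodes[0].member_seq_ids) == 2

    def test_distinct_random_sequences_stay_apart(self):
        rng = np.random.default_rng(1)
        nodes = collapse_identical(recs([random_protein(100, rng)
                                         for _ in range(5)]))
        assert len(nodes) == 5

    def test_representative_is_longest_member(self, dataset):
        seqs = [dataset.seq(s) for s, t in dataset.truth.sequences.items()
                if t.family in {"PufL", "PufM"}]
        for node in collapse_identical(seqs):
            rep_len = len(node.representative.sequence)
            member_lens = [len(next(s for s in seqs if s.seq_id == m).sequence)
                           for m in node.member_seq_ids]
            assert rep_len == max(member_lens)

    def test_matches_brute_force_partition_on_toy_set(self):
        """Greedy longest-first collapsing reproduces the partition found by
        directly checking every sequence against every longer candidate
        representative in order (8-sequence toy set)."""
        rng = np.random.default_rng(7)
        base1 = random_protein(90, rng)
        base2 = random_protein(80, rng)
        variants = [base1, base1[:-2], base1[:45] + "W" + base1[46:],
                    base2, base2[:70], random_protein(90, rng),
                    base2[:40] + "WW" + base2[42:], base1]
        seqs = recs(variants)
        nodes = collapse_identical(seqs)
        # independent replay of the stated rule
        ordered = sorted(seqs, key=lambda r: (-len(r.sequence), r.seq_id))
        reps, members = [], {}
        for rec in ordered:
            for rep in reps:
                res = global_align(rec.sequence, rep.sequence)
                if percent_identity(res, "shorter_sequence") >= 0.95:
                    members[rep.seq_id].append(rec.seq_id)
                    break
            else:
                reps.append(rec)
                members[rec.seq_id] = [rec.seq_id]
        expected = sorted(sorted(v) for v in members.values())
        got = sorted(sorted(n.member_seq_ids) for n in nodes)
        assert got == expected


class TestAllVsAll:
    def test_row_count_is_n_choose_2(self, toy_nodes):
        table = all_vs_all_scores(toy_nodes)
        n = len(toy_nodes)
        assert len(table) == n * (n - 1) // 2

    def test_identical_representatives_score_highest(self):
        rng = np.random.default_rng(3)
        seq = random_protein(150, rng)
        nodes = collapse_identical(
            recs([seq, random_protein(150, rng), random_protein(150, rng)]))
        nodes[1].representative = SeqRecordX("dup", seq)  # force identical reps
        table = all_vs_all_scores(nodes)
        top = table.sort_values("alignment_score").iloc[-1]
        assert {top["node1"], top["node2"]} \
            == {nodes[0].node_id, nodes[1].node_id}

    def test_symmetric_under_sequence_swap(self, toy_nodes):
        table = all_vs_all_scores(toy_nodes)
        swapped = all_vs_all_scores(list(reversed(toy_nodes)))
        def canon(t):
            return {frozenset((a, b)): round(s, 9)
                    for a, b, s in t.itertuples(index=False)}
        assert canon(table) == canon(swapped)


class TestThresholding:
    def test_threshold_above_max_gives_all_singletons(self, toy_nodes):
        table = all_vs_all_scores(toy_nodes)
        ssn = build_ssn(toy_nodes, table, table["alignment_score"].max() + 1)
        assert ssn.edges == []
        assert set(ssn.clusters.values()) == {"singleton"}

    def test_edges_nested_across_thresholds(self, pipeline):
        """Every edge kept at AS 80 is kept at AS 50 (same score table)."""
        e80 = {(a, b) for a, b, _ in pipeline.ssns[80.0].edges}
        e50 = {(a, b) for a, b, _ in pipeline.ssns[50.0].edges}
        assert e80 <= e50

    def test_component_count_nondecreasing_in_threshold(self, toy_nodes):
        table = all_vs_all_scores(toy_nodes)
        counts = []
        for thr in (0, 10, 50, 100, 200):
            ssn = build_ssn(toy_nodes, table, thr)
            comps = {c for c in ssn.clusters.values()}
            counts.append(len({c for c in comps if c != "singleton"})
                          + sum(1 for v in ssn.clusters.values()
                                if v == "singleton"))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestClusters:
    def test_two_planted_families_two_clusters(self):
        rng = np.random.default_rng(11)
        fam1 = random_protein(150, rng)
        fam2 = random_protein(150, rng)
        seqs = []
        for i in range(3):
            mutated1 = fam1[:i * 10] + "A" + fam1[i * 10 + 1:]
            mutated2 = fam2[:i * 10] + "A" + fam2[i * 10 + 1:]
            seqs += [SeqRecordX(f"f1_{i}", mutated1),
                     SeqRecordX(f"f2_{i}", mutated2)]
        nodes = collapse_identical(seqs, id_threshold=0.999)
        ssn = build_ssn(nodes, all_vs_all_scores(nodes), 50.0)
        clusters = {c for c in ssn.clusters.values() if c != "singleton"}
        assert len(clusters) == 2

    def test_fully_connected_toy_graph_is_one_cluster(self, toy_nodes):
        table = all_vs_all_scores(toy_nodes)
        ssn = build_ssn(toy_nodes, table, 0.0)
        assert len(set(ssn.clusters.values())) == 1

    def test_default_simulation_recovers_eight_clusters(self, pipeline):
        """4 PufL-analog + 4 PufM-analog clades emerge as 8 clusters."""
        ssn = pipeline.ssns[80.0]
        clusters = {c for c in ssn.clusters.values() if c != "singleton"}
        assert len(clusters) == 8

    def test_cluster_partition_matches_truth_clades(self, pipeline, dataset):
        """Restricted to non-fragment members, each cluster holds exactly
        one (family, clade) group."""
        ssn = pipeline.ssns[80.0]
        seen = {}
        for node in nonsingleton_nodes(ssn):
            cluster = ssn.clusters[node.node_id]
            for sid in node.member_seq_ids:
                base = sid[2:] if sid.startswith(("N_", "C_")) else sid
                if dataset.truth.sequences[base].fragment:
                    continue
                group = true_group(dataset.truth, sid)
                seen.setdefault(cluster, set()).add(group)
        assert all(len(groups) == 1 for groups in seen.values())
        assert len({g for groups in seen.values() for g in groups}) == 8

    def test_outgroup_never_shares_a_component_with_puf(self, pipeline,
                                                        dataset):
        """At the discrimination threshold the PsbA/PsbD-like family falls
        in components disjoint from every Puf-family node."""
        ssn = pipeline.ssns[90.0]
        outgroup_families = {"PsbA-like", "PsbD-like"}
        for a, b, _ in ssn.edges:
            kinds = set()
            for node_id in (a, b):
                node = ssn.node(node_id)
                for sid in node.member_seq_ids:
                    base = sid[2:] if sid.startswith(("N_", "C_")) else sid
                    fam = dataset.truth.sequences[base].family
                    kinds.add("psb" if fam in outgroup_families else "puf")
            assert kinds != {"psb", "puf"}
        clusters_by_kind = {}
        for node in ssn.nodes:
            label = ssn.clusters[node.node_id]
            if label == "singleton":
                continue
            for sid in node.member_seq_ids:
                base = sid[2:] if sid.startswith(("N_", "C_")) else sid
                fam = dataset.truth.sequences[base].family
                kind = "psb" if fam in outgroup_families else "puf"
                clusters_by_kind.setdefault(label, set()).add(kind)
        assert all(len(k) == 1 for k in clusters_by_kind.values())


class TestComposition:
    def test_single_taxon_cluster_is_100_percent(self, toy_nodes):
        for n in toy_nodes:
            n.taxon = "Chloroflexota"
        table = all_vs_all_scores(toy_nodes)
        ssn = build_ssn(toy_nodes, table, 0.0)
        comp = cluster_composition(ssn)
        assert (comp["percent_nodes"] == 100.0).all()

    def test_two_to_one_split_percentages(self):
        rng = np.random.default_rng(21)
        seq = random_protein(100, rng)
        seqs = [SeqRecordX(f"n{i}", seq[:i] + "W" * 3 + seq[i + 3:])
                for i in range(3)]
        for i, s in enumerate(seqs):
            s.taxon = "A" if i < 2 else "B"
        nodes = collapse_identical(seqs, id_threshold=0.999)
        ssn = build_ssn(nodes, all_vs_all_scores(nodes), 10.0)
        comp = cluster_composition(ssn)
        assert sorted(comp["percent_nodes"]) == [33.3, 66.7]

    def test_percentages_sum_to_100(self, pipeline):
        comp = pipeline.composition
        for _, group in comp.groupby("cluster"):
            assert group["percent_nodes"].sum() == pytest.approx(100.0,
                                                                 abs=0.1)


class TestExport:
    @pytest.mark.parametrize("fmt,suffix", [("graphml", ".graphml"),
                                            ("xgmml", ".xgmml"),
                                            ("tsv", ".tsv")])
    def test_round_trip_preserves_graph_and_attributes(self, pipeline,
                                                       tmp_path, fmt, suffix):
        ssn = pipeline.ssns[80.0]
        path = tmp_path / f"net{suffix}"
        export_network(ssn, path, fmt)
        g = read_network(path, fmt)
        assert g.number_of_nodes() == len(ssn.nodes)
        assert g.number_of_edges() == len(ssn.edges)
        expected = ssn.graph()
        assert nx.is_isomorphic(g, expected)
        some_node = ssn.nodes[0]
        attrs = g.nodes[some_node.node_id]
        assert attrs["taxon"] == (some_node.taxon or "")
        assert str(attrs["cluster"]) == str(ssn.clusters[some_node.node_id])

    def test_empty_network_exports_cleanly(self, tmp_path):
        from pufminer.ssn import SSN
        empty = SSN(nodes=[], edges=[], threshold=50.0)
        for fmt, name in (("graphml", "e.graphml"), ("xgmml", "e.xgmml"),
                          ("tsv", "e.tsv")):
            export_network(empty, tmp_path / name, fmt)
            g = read_network(tmp_path / name, fmt)
            assert g.number_of_nodes() == 0

    def test_unknown_format_rejected(self, pipeline, tmp_path):
        with pytest.raises(ValueError):
            export_network(pipeline.ssns[80.0], tmp_path / "x", "dot")
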