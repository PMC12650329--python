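"""Synthetic-data generator: determinism, planted signal, round trips."""

import statistics

import dendropy
import numpy as np
import pytest

from pufminer.align import global_align, percent_identity
from pufminer.simulate import (ConfigurationError, SimConfig,
                               evolve_along_tree, generate_dataset,
                               mutate_sequence, random_protein, read_dataset,
                               simulate_guide_trees, write_dataset)

from oracles import expected_pairwise_identity


class TestSimConfig:
    def test_defaults_are_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize("bad", [
        dict(fragment_fraction=1.5),
        dict(within_clade_divergence=0.7),          # breaks the ordering
        dict(n_clades_pufL=0),
        dict(fusion_clade_indices=frozenset({9})),
        dict(architecture_mix=(("A", -1.0), ("B", 2.0))),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SimConfig(**bad).validate()


class TestGuideTrees:
    def test_leaf_and_stem_counts(self):
        cfg = SimConfig(seqs_per_clade=5)
        tree_l, tree_m, tree_og = simulate_guide_trees(cfg)
        assert len(tree_l.leaf_nodes()) == 4 * 5
        stems = [c for c in tree_l.seed_node.child_nodes()]
        assert len(stems) == 4
        assert all(s.edge.length == cfg.between_clade_divergence for s in stems)
        leaves = tree_l.leaf_nodes()
        assert all(lf.edge.length == cfg.within_clade_divergence for lf in leaves)

    def test_degenerate_single_leaf_clade(self):
        cfg = SimConfig(n_clades_pufL=1, n_clades_pufM=1, seqs_per_clade=1,
                        fusion_clade_indices=frozenset(),
                        novel_clade_indices=frozenset())
        tree_l, _, _ = simulate_guide_trees(cfg)
        assert len(tree_l.leaf_nodes()) == 1

    def test_same_seed_same_newick(self):
        a = simulate_guide_trees(SimConfig())[0].as_string(schema="newick")
        b = simulate_guide_trees(SimConfig())[0].as_string(schema="newick")
        assert a == b


class TestEvolveAlongTree:
    def _two_leaf_tree(self, branch):
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        for label in ("x", "y"):
            node = dendropy.Node(edge_length=branch)
            node.taxon = taxa.new_taxon(label=label)
            tree.seed_node.add_child(node)
        return tree

    def test_zero_branch_lengths_reproduce_root(self):
        tree = self._two_leaf_tree(0.0)
        root = random_protein(80, np.random.default_rng(0))
        leaves = evolve_along_tree(tree, root, seed=5)
        assert leaves == {"x": root, "y": root}

    def test_rejects_non_amino_acid_root(self):
        with pytest.raises(ValueError):
            evolve_along_tree(self._two_leaf_tree(0.1), "MKV1", seed=0)

    def test_determinism(self):
        tree = self._two_leaf_tree(0.3)
        root = random_protein(120, np.random.default_rng(1))
        assert (evolve_along_tree(tree, root, seed=9)
                == evolve_along_tree(tree, root, seed=9))

    def test_mean_identity_matches_closed_form(self):
        """Monte-Carlo identity between two leaves at branch length b each
        matches (1-p)^2 + p^2/19 with p = 1 - exp(-b)."""
        b = 0.3
        tree = self._two_leaf_tree(b)
        root = random_protein(200, np.random.default_rng(2))
        idents = []
        for rep in range(200):
            leaves = evolve_along_tree(tree, root, seed=1000 + rep)
            x, y = leaves["x"], leaves["y"]
            idents.append(sum(1 for p, q in zip(x, y) if p == q) / len(x))
        expected = expected_pairwise_identity(b)
        sem = statistics.stdev(idents) / len(idents) ** 0.5
        assert abs(statistics.mean(idents) - expected) < 4 * max(sem, 1e-4)


class TestPlantedDataset:
    def test_byte_identical_outputs_for_same_config(self, tmp_path):
        cfg = SimConfig(rng_seed=33)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(cfg), d1)
        write_dataset(generate_dataset(cfg), d2)
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_fusion_truth_intervals(self, dataset):
        for sid, t in dataset.truth.sequences.items():
            if t.family == "fusion" and not t.fragment:
                assert len(t.domains) == 2
                (s1, e1), (s2, e2) = t.domains
                assert s1 == 1 and s2 == e1 + 11  # 10-mer linker gap
                assert e2 == len(dataset.seq(sid).sequence)

    def test_truth_domains_inside_sequences(self, dataset):
        for sid, t in dataset.truth.sequences.items():
            n = len(dataset.seq(sid).sequence)
            for (s, e) in t.domains:
                assert 1 <= s <= e <= n

    def test_every_protein_maps_to_one_bin(self, dataset):
        bin_ids = {b.bin_id for b in dataset.bins}
        assert all(p.bin_id in bin_ids for p in dataset.proteins)

    def test_fragment_fraction_zero_means_no_fragments(self):
        ds = generate_dataset(SimConfig(rng_seed=4, fragment_fraction=0.0))
        assert not any(t.fragment for t in ds.truth.sequences.values())

    def test_missing_temperature_count_is_deterministic(self):
        ds = generate_dataset(SimConfig(rng_seed=5, missing_temp_fraction=0.2))
        n_missing = sum(1 for b in ds.bins if b.temperature_c is None)
        assert n_missing == round(0.2 * len(ds.bins))

    def test_planted_identity_ordering(self, dataset):
        """Mean within-clade identity > between-clade > family-vs-outgroup."""
        truth = dataset.truth.sequences

        def members(family, clade):
            return [dataset.seq(s).sequence for s, t in truth.items()
                    if t.family == family and t.clade == clade
                    and not t.fragment and not t.divergent][:3]

        def mean_ident(group_a, group_b):
            vals = [percent_identity(global_align(a, b), "aligned_positions")
                    for a in group_a for b in group_b if a != b]
            return statistics.mean(vals)

        l0, l2 = members("PufL", 0), members("PufL", 2)
        og = [dataset.seq(s).sequence for s, t in truth.items()
              if t.family == "PsbA-like"][:3]
        within = mean_ident(l0, l0)
        between = mean_ident(l0, l2)
        vs_outgroup = mean_ident(l0, og)
        assert within > between > vs_outgroup

    def test_dataset_round_trip(self, dataset, tmp_path):
        write_dataset(dataset, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert back.config == dataset.config
        assert {p.seq_id: p.sequence for p in back.proteins} \
            == {p.seq_id: p.sequence for p in dataset.proteins}
        assert back.truth.bins == dataset.truth.bins
        assert back.truth.contigs == dataset.truth.contigs
        assert len(back.features) == len(dataset.features)
        assert back.outgroup_refs == dataset.outgroup_refs
        for sid, t in dataset.truth.sequences.items():
            assert back.truth.sequences[sid] == t

    def test_empty_write_read(self, tmp_path):
        ds = generate_dataset(SimConfig(rng_seed=6))
        ds.bins, ds.proteins, ds.features = [], [], []
        ds.truth.sequences, ds.truth.bins, ds.truth.contigs = {}, {}, {}
        write_dataset(ds, tmp_path / "empty")
        back = read_dataset(tmp_path / "empty")
        assert back.proteins == [] and back.bins == []


def test_mutate_zero_branch_is_identity():
    rng = np.random.default_rng(0)
    seq = random_protein(50, rng)
    assert mutate_sequence(seq, 0.0, rng) == seq
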