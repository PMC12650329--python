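"""Uniqueness accounting and end-to-end pipeline orchestration.

``run_pipeline`` chains every stage of the survey: temperature curation →
homolog identification (profile + pairwise union) → fusion-domain splitting
→ 95 %-identity node collapsing → a discrimination network that separates
the Puf families from the PsbA/PsbD-like outgroup → clustered networks at
the working alignment-score thresholds → progressive alignment, editing,
redundancy reduction → neighbor-joining tree with outgroup rooting →
operon-architecture classification → uniqueness against a reference set.
The manifest records the count funnel at every stage and every threshold
used, and is byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .align import local_align, percent_identity
from .curation import curate_bins
from .homologs import (DEFAULT_PAIRWISE_AS, HomologSet, find_homologs,
                       rescue_scan, split_all_fusions)
from .neighborhoods import classify_architecture
from .phylo import (build_msa, edit_msa, nj_tree, remove_redundant,
                    root_at_outgroup, annotate_tree, leaf_labels)
from .profiles import DEFAULT_BIT_THRESHOLD, build_profile
from .records import SeqRecordX
from .simulate import SimConfig, SyntheticDataset, generate_dataset
from .ssn import (SSN, all_vs_all_scores, build_ssn, cluster_composition,
                  collapse_identical, export_network, nonsingleton_nodes)

log = logging.getLogger(__name__)

UNIQUENESS_THRESHOLD = 0.95


@dataclass
class UniquenessRecord:
    query_id: str
    best_reference_id: str | None
    best_identity: float
    unique: bool
    category: str = ""


def uniqueness_report(queries: list[SeqRecordX],
                      references: list[SeqRecordX],
                      threshold: float = UNIQUENESS_THRESHOLD,
                      categories: dict | None = None) -> list[UniquenessRecord]:
    """Flag queries with no reference at or above ``threshold`` identity.

    Identity is local-alignment identity over the shorter sequence; a query
    is "unique" only when its best identity is strictly below the threshold
    (a hit at exactly the threshold is not unique)."""
    if not references:
        raise ValueError("reference set is empty")
    out = []
    for q in queries:
        best_id, best_ref = 0.0, None
        for r in references:
            res = local_align(q.sequence, r.sequence)
            ident = (percent_identity(res, "shorter_sequence")
                     if res.aligned_pairs else 0.0)
            if ident > best_id:
                best_id, best_ref = ident, r.seq_id
        out.append(UniquenessRecord(
            query_id=q.seq_id, best_reference_id=best_ref,
            best_identity=best_id, unique=best_id < threshold,
            category=(categories or {}).get(q.seq_id, "")))
    return out


@dataclass
class PipelineConfig:
    """All knobs of one survey run, echoed into the manifest."""

    sim: SimConfig = field(default_factory=SimConfig)
    t_min: float = 42.0
    t_max: float = 90.0
    profile_threshold: float = DEFAULT_BIT_THRESHOLD
    pairwise_threshold: float = DEFAULT_PAIRWISE_AS
    discrimination_as: float = 90.0
    ssn_as_levels: tuple = (50.0, 80.0)
    tree_as: float = 80.0
    id_collapse: float = 0.95
    uniqueness_threshold: float = UNIQUENESS_THRESHOLD
    min_row_coverage: float = 0.6
    max_col_gap_fraction: float = 0.5
    redundancy_threshold: float = 0.95
    rescue_threshold: float = 5.0


@dataclass
class PipelineResult:
    manifest: dict
    curation: object = None
    homologs: HomologSet | None = None
    domain_seqs: list = field(default_factory=list)
    ssns: dict = field(default_factory=dict)       # threshold -> SSN
    composition: pd.DataFrame | None = None
    tree: object = None
    annotation: pd.DataFrame | None = None
    newick: str = ""
    architecture_calls: dict = field(default_factory=dict)   # bin -> call
    uniqueness: list = field(default_factory=list)
    rescue: list = field(default_factory=list)


def run_pipeline(config: PipelineConfig | None = None,
                 dataset: SyntheticDataset | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full survey on ``dataset`` (generated from ``config.sim`` when
    not supplied).  Deterministic for a fixed configuration."""
    config = config or PipelineConfig()
    t_start = time.time()
    manifest: dict = {"thresholds": {
        "t_min": config.t_min, "t_max": config.t_max,
        "profile_bits": config.profile_threshold,
        "pairwise_as": config.pairwise_threshold,
        "discrimination_as": config.discrimination_as,
        "ssn_as_levels": list(config.ssn_as_levels),
        "tree_as": config.tree_as,
        "identity_collapse": config.id_collapse,
        "uniqueness_identity": config.uniqueness_threshold,
        "rng_seed": config.sim.rng_seed,
    }, "stages": {}}
    result = PipelineResult(manifest=manifest)

    def stage(name, **counts):
        manifest["stages"][name] = {**counts,
                                    "elapsed_s": round(time.time() - t_start, 2)}
        log.info("stage %-18s %s", name, counts)

    if dataset is None:
        dataset = generate_dataset(config.sim)
    truth = dataset.truth

    # 1. curation ---------------------------------------------------------
    metadata = pio.metadata_frame(dataset.bins)
    curation = curate_bins(metadata, config.t_min, config.t_max)
    result.curation = curation
    kept_bins = set(curation.kept)
    proteins = [p for p in dataset.proteins if p.bin_id in kept_bins]
    stage("curation", n_bins=len(dataset.bins), n_bins_kept=len(kept_bins),
          n_proteins=len(proteins))
    if not proteins:
        stage("end", status="empty input; nothing to analyse")
        return result

    # 2. homolog search ----------------------------------------------------
    rc_profile = build_profile(dataset.rc_seed, name="RC_domain")
    ompa_profile = build_profile(dataset.ompa_seed, name="OmpA_like")
    homologs = find_homologs(proteins, rc_profile, dataset.seed_queries(),
                             config.profile_threshold, config.pairwise_threshold)
    result.homologs = homologs
    stage("homolog_search", n_homologs=len(homologs),
          n_by_profile=len(homologs.by_profile),
          n_by_pairwise=len(homologs.by_pairwise),
          n_fusions=len(homologs.fusion_ids))

    # 3. fusion splitting --------------------------------------------------
    domain_seqs = split_all_fusions(homologs)
    result.domain_seqs = domain_seqs
    stage("fusion_splitting", n_domain_seqs=len(domain_seqs))

    # 4. 95% collapse and discrimination network ---------------------------
    nodes = collapse_identical(domain_seqs, config.id_collapse)
    if len(nodes) < 2:
        stage("end", status="fewer than 2 nodes; no network possible")
        return result
    edge_table = all_vs_all_scores(nodes)
    ssn_disc = build_ssn(nodes, edge_table, config.discrimination_as)
    outgroup_ref_set = set(dataset.outgroup_refs)
    psb_clusters = {ssn_disc.clusters[n.node_id] for n in ssn_disc.nodes
                    if set(n.member_seq_ids) & outgroup_ref_set}
    psb_clusters.discard("singleton")
    puf_nodes = [n for n in ssn_disc.nodes
                 if ssn_disc.clusters[n.node_id] not in psb_clusters
                 and not (set(n.member_seq_ids) & outgroup_ref_set)]
    result.ssns[config.discrimination_as] = ssn_disc
    stage("discrimination", n_nodes=len(nodes),
          n_psb_clusters=len(psb_clusters),
          n_puf_nodes=len(puf_nodes))

    # 5. working networks at 50/80 ----------------------------------------
    node_ids = {n.node_id for n in puf_nodes}
    puf_edges = edge_table[edge_table["node1"].isin(node_ids)
                           & edge_table["node2"].isin(node_ids)]
    for level in config.ssn_as_levels:
        ssn = build_ssn(puf_nodes, puf_edges, level)
        result.ssns[level] = ssn
        n_clusters = len({c for c in ssn.clusters.values() if c != "singleton"})
        stage(f"ssn_{int(level)}", n_edges=len(ssn.edges),
              n_clusters=n_clusters,
              n_nonsingleton_nodes=len(nonsingleton_nodes(ssn)))
    ssn_tree = result.ssns[config.tree_as]
    result.composition = cluster_composition(ssn_tree)

    # 6. alignment, editing, redundancy, tree ------------------------------
    reps = [n.representative for n in nonsingleton_nodes(ssn_tree)]
    outgroup = [p for p in dataset.proteins if p.seq_id in outgroup_ref_set]
    tree = None
    if len(reps) >= 3:
        msa = build_msa(reps + outgroup)
        msa_edit = edit_msa(msa, config.min_row_coverage,
                            config.max_col_gap_fraction)
        msa_nr = remove_redundant(msa_edit, config.redundancy_threshold)
        stage("alignment", n_rows=len(msa.ids), n_after_editing=len(msa_edit.ids),
              n_after_redundancy=len(msa_nr.ids),
              n_columns=msa_nr.n_columns)
        outgroup_in = [s for s in msa_nr.ids if s in outgroup_ref_set]
        if len(msa_nr.ids) >= 3 and outgroup_in:
            tree = root_at_outgroup(nj_tree(msa_nr), outgroup_in)
    if tree is not None:
        result.tree = tree
        ingroup_leaves = [l for l in leaf_labels(tree)
                          if l not in outgroup_ref_set]
        stage("tree", n_leaves=len(leaf_labels(tree)),
              n_ingroup_leaves=len(ingroup_leaves))
    else:
        ingroup_leaves = []
        stage("tree", n_leaves=0, n_ingroup_leaves=0)

    # 7. neighborhoods / architectures ------------------------------------
    calls = {}
    for bin_id in sorted(kept_bins):
        feats = [f for f in dataset.features
                 if f.contig_id.rsplit("_c", 1)[0] == bin_id]
        if any(f.label in {"pufL", "pufM", "pufLM_fusion"} for f in feats):
            calls[bin_id] = classify_architecture(feats)
    result.architecture_calls = calls
    stage("neighborhoods", n_genomes_classified=len(calls))

    # 8. uniqueness --------------------------------------------------------
    rep_by_leaf = {n.representative.seq_id: n for n in ssn_tree.nodes}
    queries = [rep_by_leaf[l].representative for l in ingroup_leaves
               if l in rep_by_leaf and rep_by_leaf[l].hot_spring]
    uniqueness = []
    if queries and dataset.references:
        cats = {n.representative.seq_id: str(ssn_tree.clusters.get(n.node_id, ""))
                for n in ssn_tree.nodes}
        uniqueness = uniqueness_report(queries, dataset.references,
                                       config.uniqueness_threshold, cats)
    result.uniqueness = uniqueness
    stage("uniqueness", n_queries=len(queries),
          n_unique=sum(1 for u in uniqueness if u.unique))

    # 9. rescue scan for divergent singletons ------------------------------
    divergent = [p for p in dataset.proteins
                 if truth.sequences.get(p.seq_id) is not None
                 and truth.sequences[p.seq_id].divergent]
    rescue = []
    if divergent:
        rescue = rescue_scan(proteins, divergent[0], config.rescue_threshold,
                             homologs)
        # a protein is represented in the tree through its node's
        # representative; a fusion through its split domains
        parent_of = {d.seq_id: d.parent_id for d in domain_seqs if d.parent_id}
        in_tree = set()
        for n in nonsingleton_nodes(ssn_tree):
            for sid in n.member_seq_ids:
                in_tree.add(sid)
                if sid in parent_of:
                    in_tree.add(parent_of[sid])
        stage("rescue", n_hits=len(rescue),
              n_not_in_tree=sum(1 for h in rescue if h.seq_id not in in_tree))
    result.rescue = rescue

    manifest["funnel"] = {
        "bins_kept": len(kept_bins),
        "homologs": len(homologs),
        "fusions": len(homologs.fusion_ids),
        "domain_seqs": len(domain_seqs),
        "nodes": len(nodes),
        "puf_nodes": len(puf_nodes),
        "nonsingleton_nodes": len(nonsingleton_nodes(ssn_tree)),
        "tree_leaves_ingroup": len(ingroup_leaves),
        "unique": sum(1 for u in uniqueness if u.unique),
    }

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, result, dataset)
    return result


def _write_outputs(out: Path, config: PipelineConfig, result: PipelineResult,
                   dataset: SyntheticDataset) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1,
                                                  sort_keys=True))
    if result.curation is not None:
        pd.DataFrame({"bin_id": result.curation.kept, "status": "kept"}
                     ).to_csv(out / "curation_kept.tsv", sep="\t", index=False)
        pd.DataFrame(result.curation.excluded, columns=["bin_id", "reason"]
                     ).to_csv(out / "curation_excluded.tsv", sep="\t", index=False)
    for level, ssn in result.ssns.items():
        export_network(ssn, out / f"ssn_as{int(level)}.graphml", "graphml")
    if result.composition is not None:
        result.composition.to_csv(out / "cluster_composition.tsv", sep="\t",
                                  index=False)
    if result.domain_seqs:
        pio.write_fasta(result.domain_seqs, out / "domain_seqs.faa")
    if result.tree is not None:
        meta = {}
        ssn_tree = result.ssns.get(config.tree_as)
        uniq = {u.query_id: u.unique for u in result.uniqueness}
        for n in ssn_tree.nodes:
            sid = n.representative.seq_id
            meta[sid] = {"cluster": ssn_tree.clusters.get(n.node_id, ""),
                         "phylum": (n.taxon or "").split(";")[0],
                         "hot": bool(n.hot_spring),
                         "unique": uniq.get(sid, False)}
        for p in dataset.proteins:
            if p.seq_id in dataset.outgroup_refs:
                meta[p.seq_id] = {"cluster": "outgroup",
                                  "phylum": (p.taxon or "").split(";")[0],
                                  "hot": bool(p.hot_spring)}
        table, newick, itol = annotate_tree(result.tree, meta)
        result.annotation, result.newick = table, newick
        (out / "tree.nwk").write_text(newick + "\n")
        table.to_csv(out / "tree_annotations.tsv", sep="\t", index=False)
        (out / "tree_itol.txt").write_text(itol + "\n")
    if result.architecture_calls:
        pd.DataFrame([{"genome": b, "architecture": c.short,
                       "evidence": ",".join(c.evidence)}
                      for b, c in sorted(result.architecture_calls.items())]
                     ).to_csv(out / "architectures.tsv", sep="\t", index=False)
    if result.uniqueness:
        pd.DataFrame([u.__dict__ for u in result.uniqueness]
                     ).to_csv(out / "uniqueness.tsv", sep="\t", index=False)
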