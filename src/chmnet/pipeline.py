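"""Pipeline stages tying the library into one reproducible run.

Each stage reads declared inputs from the run directory and writes declared
outputs there, so stages can be rerun independently; ``run_all`` chains them.
Every run writes a resolved-config snapshot.  All artifacts are plain text
(CSV / TSV / GMT / GraphML / YAML) and byte-identical across reruns with the
same configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import arm, cohort, enrich, io, network, pharm, reference, synthetic

log = logging.getLogger("chmnet")

__all__ = [
    "stage_simulate",
    "stage_cohort",
    "stage_mine",
    "stage_network",
    "stage_pharm",
    "stage_enrich",
    "stage_compare",
    "run_all",
]

# Planted pathway-coverage layout for the demo run: (count, category path,
# covering groups).  Immune-system blocks mirror the published complementary
# pattern (innate/adaptive coverage by the herb network, interleukin-heavy
# cytokine coverage by the comparator drugs); overall planted coverage is
# 140 pathways for the herb network and 55 for the comparator set.
DEMO_PATHWAY_BLOCKS: list[tuple[int, str, tuple[str, ...]]] = [
    (8, "Immune System/Innate Immune System", ("CHM",)),
    (6, "Immune System/Adaptive Immune System", ("CHM",)),
    (2, "Immune System/Cytokine Signaling/Interferon signaling", ("CHM",)),
    (5, "Immune System/Cytokine Signaling/Signaling by Interleukins", ("WM",)),
    (3, "Immune System/Cytokine Signaling", ("CHM", "WM")),
    (10, "Immune System/Innate Immune System", ()),
    (32, "Signal Transduction/GPCR signaling", ("CHM",)),
    (31, "Metabolism/Lipid metabolism", ("CHM",)),
    (31, "Gene Expression/Transcription", ("CHM",)),
    (10, "Signal Transduction/GPCR signaling", ("WM",)),
    (10, "Neuronal System/Transmission across synapses", ("WM",)),
    (14, "Signal Transduction/Nuclear receptors", ("CHM", "WM")),
    (13, "Hemostasis/Platelet activation", ("CHM", "WM")),
    (42, "Cell Cycle/Mitotic", ()),
    (42, "Developmental Biology/Axon guidance", ()),
    (41, "Metabolism of proteins/Post-translational modification", ()),
]


def _paths(cfg: Mapping) -> dict[str, Path]:
    out = Path(cfg["out_dir"])
    return {
        "config": out / "config.yaml",
        "cohort": out / "cohort.csv",
        "cohort_summary": out / "cohort_summary.csv",
        "prescriptions": out / "prescriptions.csv",
        "prevalence": out / "prevalence.csv",
        "rules": out / "rules.csv",
        "top_rules": out / "top_rules.csv",
        "graphml": out / "network.graphml",
        "edges": out / "network_edges.tsv",
        "clusters": out / "clusters.csv",
        "ingredients": out / "ingredients.csv",
        "ingredient_targets": out / "ingredient_targets.csv",
        "wm_drugs": out / "wm_drugs.csv",
        "wm_targets": out / "wm_targets.csv",
        "gmt": out / "pathways.gmt",
        "pathway_categories": out / "pathway_categories.csv",
        "universe": out / "protein_universe.csv",
        "cluster_targets": out / "cluster_targets.csv",
        "overlap": out / "overlap.csv",
        "overlap_counts": out / "overlap_counts.csv",
        "enrichment_chm": out / "enrichment_chm.csv",
        "enrichment_wm": out / "enrichment_wm.csv",
        "coverage_immune": out / "coverage_immune.csv",
        "coverage_all": out / "coverage_all.csv",
    }


def _meta(cfg: Mapping) -> dict:
    from . import __version__

    return {"chmnet-version": __version__, "seed": cfg["seed"]}


def _write_target_map(target_map: Mapping[str, frozenset], path: Path, meta: Mapping) -> None:
    df = pd.DataFrame(
        [(agent, "|".join(sorted(prots))) for agent, prots in sorted(target_map.items())],
        columns=["agent", "proteins"],
    )
    io.write_table(df, path, metadata=meta)


def _read_target_map(path: Path) -> dict[str, frozenset]:
    df = io.read_table(path, keep_default_na=False)
    return {
        row["agent"]: frozenset(p for p in str(row["proteins"]).split("|") if p)
        for _, row in df.iterrows()
    }


def stage_simulate(cfg: Mapping) -> None:
    """Generate every synthetic input table for the downstream stages."""
    paths = _paths(cfg)
    meta = _meta(cfg)
    seed = cfg["seed"]
    scale = cfg["n_cohort_scale"]

    cohort_spec = synthetic.default_cohort_spec(
        seed=seed,
        n_users=int(round(reference.N_USERS * scale)),
        n_nonusers=int(round(reference.N_NONUSERS * scale)),
    )
    cohort_df = synthetic.generate_cohort(cohort_spec)
    io.write_table(cohort_df, paths["cohort"], metadata=meta)
    log.info("cohort: %d rows -> %s", len(cohort_df), paths["cohort"])

    net_spec = synthetic.default_network_spec(
        seed=seed,
        n_prescriptions=cfg["n_prescriptions"],
        co_draw=cfg["co_draw"],
        background_mass=cfg["background_mass"],
        with_dose=True,
    )
    rx = synthetic.generate_prescriptions(net_spec)
    io.write_table(rx, paths["prescriptions"], metadata=meta)
    log.info("prescriptions: %d rows (mean size %.2f) -> %s",
             len(rx), arm.mean_prescription_size(rx), paths["prescriptions"])

    ing_spec = synthetic.default_ingredient_spec(seed=seed, n_proteins=cfg["n_proteins"])
    ingredients, target_map = synthetic.generate_ingredient_db(ing_spec)
    io.write_table(ingredients, paths["ingredients"], metadata=meta)
    _write_target_map(target_map, paths["ingredient_targets"], meta)
    log.info("ingredients: %d rows over %d herbs", len(ingredients), len(ing_spec.herbs))

    drug_category, wm_map = synthetic.generate_wm_targets(proteins=ing_spec.proteins, seed=seed)
    io.write_table(
        pd.DataFrame(sorted(drug_category.items()), columns=["drug", "category"]),
        paths["wm_drugs"],
        metadata=meta,
    )
    _write_target_map(wm_map, paths["wm_targets"], meta)

    # Plant pathway coverage against the screened target unions the pharm
    # stage will actually compute.
    retained = pharm.filter_ingredients(
        ingredients, ob_min=cfg["ob_min"], dl_min=cfg["dl_min"], ob_units=cfg["ob_units"]
    )
    chm_union = frozenset().union(
        *(target_map[i] for i in retained["ingredient"] if i in target_map)
    )
    wm_union = frozenset().union(*wm_map.values())
    collection = synthetic.plant_pathway_coverage(
        {"CHM": chm_union, "WM": wm_union},
        universe=ing_spec.proteins,
        blocks=DEMO_PATHWAY_BLOCKS,
        seed=seed,
    )
    io.write_gmt(collection, paths["gmt"])
    io.write_categories(collection.categories, paths["pathway_categories"])
    io.write_table(pd.DataFrame({"protein": sorted(collection.universe)}), paths["universe"], metadata=meta)
    log.info("pathways: %d sets -> %s", len(collection), paths["gmt"])


def stage_cohort(cfg: Mapping) -> None:
    paths = _paths(cfg)
    cohort_df = io.read_table(paths["cohort"])
    variables = list(reference.COHORT_COUNTS)
    summary = cohort.summarize_by_group(cohort_df, variables)
    io.write_table(summary, paths["cohort_summary"], metadata=_meta(cfg))
    log.info("cohort summary: %d rows -> %s", len(summary), paths["cohort_summary"])


def stage_mine(cfg: Mapping) -> None:
    paths = _paths(cfg)
    rx = io.read_table(paths["prescriptions"])
    rules = arm.mine_pair_rules(
        rx,
        min_support=cfg["min_support"],
        min_confidence=cfg["min_confidence"],
        min_lift=cfg["min_lift"],
    )
    if not rules:
        log.warning("no rules passed the thresholds; writing empty rule files")
    io.write_table(arm.rules_to_frame(rules), paths["rules"], metadata=_meta(cfg))
    top = arm.top_rules(rules, n=cfg["top_n"])
    io.write_table(arm.rules_to_frame(top), paths["top_rules"], metadata=_meta(cfg))

    doses = synthetic.dose_long_table(rx) if "doses" in rx.columns else None
    ranking = arm.prevalence_ranking(rx, reference.demo_herb_type_map(), dose_table=doses)
    io.write_table(ranking, paths["prevalence"], metadata=_meta(cfg))
    log.info("rules: %d mined, top %d kept", len(rules), len(top))


def stage_network(cfg: Mapping) -> None:
    paths = _paths(cfg)
    top = io.read_table(paths["top_rules"])
    if len(top) == 0:
        raise ValueError("no rules available to build a network; rerun 'mine' with laxer thresholds")
    rules = [
        arm.AssociationRule(r.antecedent, r.consequent, r.support, r.confidence, r.lift)
        for r in top.itertuples()
    ]
    prevalence_df = io.read_table(paths["prevalence"])
    prevalence = dict(zip(prevalence_df["herb"], prevalence_df["support"]))
    herb_types = dict(zip(prevalence_df["herb"], prevalence_df["herb_type"]))
    indications = {
        h: c["label"] for c in reference.DEMO_CLUSTERS for h in c["herbs"]
    }
    g = network.build_network(rules, prevalence=prevalence, herb_types=herb_types, indications=indications)
    assignment = network.detect_clusters(g, method=cfg["cluster_method"])
    cores = network.identify_core(g, assignment)
    # label each community by its members' majority indication
    for cid, nodes in assignment.clusters.items():
        labels = [g.nodes[n]["indication"] for n in nodes if g.nodes[n]["indication"]]
        if labels:
            assignment.labels[cid] = max(sorted(set(labels)), key=labels.count)
    for node, cid in assignment.membership.items():
        g.nodes[node]["cluster"] = cid
        g.nodes[node]["is_core"] = cores.get(cid) == node
    io.write_network(g, paths["graphml"])
    io.write_edge_list(g, paths["edges"])
    deg = network.degree_centrality(g)
    rows = [
        (node, cid, assignment.labels[cid], deg[node], g.nodes[node]["prevalence"], cores.get(cid) == node)
        for node, cid in sorted(assignment.membership.items(), key=lambda kv: (kv[1], kv[0]))
    ]
    io.write_table(
        pd.DataFrame(rows, columns=["herb", "cluster", "label", "degree", "prevalence", "is_core"]),
        paths["clusters"],
        metadata=_meta(cfg) | {"modularity": round(assignment.modularity, 6)},
    )
    log.info(
        "network: %d nodes, %d edges, %d clusters (Q=%.3f)",
        g.number_of_nodes(), g.number_of_edges(), assignment.n_clusters, assignment.modularity,
    )


def stage_pharm(cfg: Mapping) -> None:
    paths = _paths(cfg)
    clusters_df = io.read_table(paths["clusters"])
    membership = dict(zip(clusters_df["herb"], clusters_df["cluster"]))
    ingredients = io.read_table(paths["ingredients"])
    target_map = _read_target_map(paths["ingredient_targets"])
    retained = pharm.filter_ingredients(
        ingredients, ob_min=cfg["ob_min"], dl_min=cfg["dl_min"], ob_units=cfg["ob_units"]
    )
    log.info("ingredient screen: %d of %d retained", len(retained), len(ingredients))
    csets = pharm.cluster_targets(membership, retained, target_map)
    io.write_table(
        pd.DataFrame(
            [(cid, len(p), "|".join(sorted(p))) for cid, p in sorted(csets.items())],
            columns=["cluster", "n_proteins", "proteins"],
        ),
        paths["cluster_targets"],
        metadata=_meta(cfg),
    )

    drugs = io.read_table(paths["wm_drugs"])
    wm_map = _read_target_map(paths["wm_targets"])
    wsets = pharm.group_targets(dict(zip(drugs["drug"], drugs["category"])), wm_map)

    collection = _read_collection(paths)
    immune = frozenset().union(
        *(m for n, m in collection.pathways.items() if collection.category(n, 1) == "Immune System")
    )
    overlap = pharm.overlap_table(csets, wsets, protein_subset=immune)
    overlap.index.name = "cluster"
    io.write_table(overlap.reset_index(), paths["overlap"], metadata=_meta(cfg))
    counts = pharm.overlap_counts(csets, wsets, protein_subset=immune)
    counts.index.name = "cluster"
    io.write_table(counts.reset_index(), paths["overlap_counts"], metadata=_meta(cfg))
    log.info("overlap table: %d clusters x %d comparator categories", *overlap.shape)


def _read_collection(paths: Mapping[str, Path]) -> enrich.PathwayCollection:
    universe = io.read_table(paths["universe"])["protein"]
    return enrich.PathwayCollection(
        pathways=io.read_gmt(paths["gmt"]).pathways,
        categories=io.read_categories(paths["pathway_categories"]),
        universe=frozenset(universe),
    )


def stage_enrich(cfg: Mapping) -> None:
    paths = _paths(cfg)
    collection = _read_collection(paths)
    ctable = io.read_table(paths["cluster_targets"], keep_default_na=False)
    chm_union = frozenset().union(
        *(frozenset(p for p in str(r["proteins"]).split("|") if p) for _, r in ctable.iterrows())
    )
    wm_union = frozenset().union(*_read_target_map(paths["wm_targets"]).values())
    for name, targets, out in (
        ("CHM", chm_union, paths["enrichment_chm"]),
        ("WM", wm_union, paths["enrichment_wm"]),
    ):
        res = enrich.run_ora(targets, collection, alpha=cfg["alpha"], method=cfg["correction"])
        io.write_table(res, out, metadata=_meta(cfg))
        log.info("%s: %d targets, %d pathways tested, %d covered",
                 name, len(targets), len(res), int(res["covered"].sum()))


def stage_compare(cfg: Mapping) -> None:
    paths = _paths(cfg)
    results = {
        "CHM": io.read_table(paths["enrichment_chm"]),
        "WM": io.read_table(paths["enrichment_wm"]),
    }
    immune = enrich.compare_coverage(results, category_filter="Immune System")
    io.write_table(immune, paths["coverage_immune"], metadata=_meta(cfg))
    everything = enrich.compare_coverage(results, category_filter=None)
    io.write_table(everything, paths["coverage_all"], metadata=_meta(cfg))
    log.info("coverage comparison: %d immune rows, %d total rows", len(immune), len(everything))


STAGES = {
    "simulate": stage_simulate,
    "cohort": stage_cohort,
    "mine": stage_mine,
    "network": stage_network,
    "pharm": stage_pharm,
    "enrich": stage_enrich,
    "compare": stage_compare,
}


def run_all(cfg: Mapping) -> None:
    io.dump_config(cfg, _paths(cfg)["config"])
    for name, stage in STAGES.items():
        log.info("=== stage: %s ===", name)
        stage(cfg)
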