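"""End-to-end orchestration of the structural-vs-genomic connectome pipeline.

``run_pipeline`` chains the stages on a synthetic configuration:
simulate -> reach probability -> connection threshold -> region-pair
classification -> TTC -> bipartite modules -> pathway enrichment ->
pathway interaction -> blood gene-set association.  It exists for smoke
testing, the command-line interface and reproduction runs; each stage is
equally usable on its own with file inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from connectosync import (
    bipartite,
    blood_association,
    pathway_enrichment,
    pathway_interaction,
    reach_probability as rp,
    synthetic_data as syn,
    ttc as ttc_mod,
)


@dataclass
class PipelineResult:
    reach_matrix: pd.DataFrame
    connections: rp.ConnectionSet
    classes: rp.RegionPairClasses
    ttc_results: list[ttc_mod.TTCResult]
    ttc_counts: pd.DataFrame
    module_sets: dict[str, bipartite.ModuleSet]
    qb: dict[str, float]
    enrichment: pathway_enrichment.EnrichmentMatrix
    interaction: dict[str, Any] = field(default_factory=dict)
    blood: blood_association.PermutationResult | None = None


def _pathway_db_from_blood(
    blood: syn.BloodDataset, background_n: int
) -> pathway_enrichment.PathwayDB:
    return pathway_enrichment.PathwayDB(
        gene_sets={k: frozenset(v) for k, v in blood.gene_sets.items()},
        categories={
            k: ("signaling" if k == blood.target_set else "metabolism")
            for k in blood.gene_sets
        },
        signaling_subtypes={
            k: ("immune" if k == blood.target_set else "none")
            for k in blood.gene_sets
        },
        background_n=background_n,
    )


def expression_pathway_db(
    config: syn.SyntheticConfig, n_pathways: int = 12, set_size: int = 25
) -> pathway_enrichment.PathwayDB:
    """Deterministic pathway catalog over the synthetic expression genes.

    Consecutive gene windows form the gene sets, so planted sync blocks
    (which also occupy consecutive genes) load onto the early pathways; the
    categories alternate so category tests are exercised.
    """
    genes = [f"G{i:04d}" for i in range(config.n_genes_per_region)]
    gene_sets = {}
    categories = {}
    subtypes = {}
    cats = pathway_enrichment.PATHWAY_CATEGORIES
    for i in range(n_pathways):
        start = (i * set_size // 2) % max(1, len(genes) - set_size)
        pid = f"PW{i:03d}"
        gene_sets[pid] = frozenset(genes[start : start + set_size])
        categories[pid] = cats[i % len(cats)]
        subtypes[pid] = "immune" if categories[pid] == "signaling" else "none"
    return pathway_enrichment.PathwayDB(
        gene_sets=gene_sets,
        categories=categories,
        signaling_subtypes=subtypes,
        background_n=config.n_genes_per_region,
    )


def run_pipeline(
    config: syn.SyntheticConfig,
    ttc_alpha: float = 1e-8,
    min_module_edges: int = 50,
    threshold_mode: str = "ecdf_reflection",
    ad_tracts: tuple[str, ...] | None = None,
    n_perm: int = 999,
    fdr: float = 0.05,
) -> PipelineResult:
    """Run every stage on freshly simulated data; deterministic in the seed."""
    labels = syn.generate_label_volume(config)
    tracts = syn.generate_tract_volumes(config, labels)
    reach = rp.reach_probability_matrix(tracts, labels)
    conn = rp.connection_threshold(reach, mode=threshold_mode, cutoff=0.002)
    if ad_tracts is None:
        ad_tracts = tuple(config.tract_ids[:1])
    classes = rp.classify_region_pairs(
        conn, syn.default_region_map(config), ad_tracts=ad_tracts
    )

    expr_set, _ = syn.generate_region_expression(config)
    results = ttc_mod.ttc_all(expr_set, alpha=ttc_alpha)
    counts = ttc_mod.count_table(results)

    db = expression_pathway_db(config)
    module_sets = {}
    qb = {}
    gene_lists: dict[tuple[str, str], list[str]] = {}
    for res in results:
        if res.count == 0:
            gene_lists[(res.pair_id, "ROI1")] = []
            gene_lists[(res.pair_id, "ROI2")] = []
            continue
        graph = bipartite.BipartiteGraph.from_ttc(res)
        labeling = bipartite.lpab_plus(graph, n_restarts=5, seed=config.seed)
        mods = bipartite.select_modules(labeling, graph, min_module_edges)
        module_sets[res.pair_id] = mods
        qb[res.pair_id] = labeling.qb
        gene_lists[(res.pair_id, "ROI1")] = mods.pooled_bottom
        gene_lists[(res.pair_id, "ROI2")] = mods.pooled_top

    enrichment = pathway_enrichment.enrich_all(gene_lists, db, fdr=fdr)

    interaction: dict[str, Any] = {}
    adjacencies = pathway_interaction.all_adjacencies(
        enrichment, db.pathway_ids
    )
    props = pathway_interaction.group_proportions(adjacencies, classes)
    interaction["proportions"] = props
    sync = pathway_enrichment.synchronization_type(enrichment)
    interaction["sync"] = sync
    for group in (rp.TRACT_BOUND, rp.AD_TRACT_BOUND):
        if (
            props.sizes.get(group, 0) >= 2
            and props.sizes.get(rp.NOT_BOUND, 0) >= 2
        ):
            p_mat, neglog = pathway_interaction.chisq_compare(props, group)
            interaction[f"chisq_p:{group}"] = p_mat
            interaction[f"graph:{group}"] = pathway_interaction.build_graph(
                p_mat, db.pathway_ids, group=group
            )
            interaction[f"sync_test:{group}"] = (
                pathway_interaction.symmetric_sync_test(sync, classes, group)
            )

    blood_res = None
    blood_ds, _ = syn.generate_blood_dataset(config)
    genes = blood_association.mean_max_collapse(
        blood_ds.probes, blood_ds.probe_map
    )
    if config.geneset_effect is not None:
        _, measure_col, _ = config.geneset_effect
    else:
        measure_col = (
            f"{config.pheno_tracts[0]}:{config.measures[0]}"
        )
    blood_res = blood_association.sumchisq_permutation(
        genes,
        blood_ds.gene_sets[blood_ds.target_set],
        blood_ds.phenotypes[measure_col].to_numpy(),
        blood_ds.covariates,
        n_perm=n_perm,
        seed=config.seed,
        measure_name=measure_col,
    )

    return PipelineResult(
        reach_matrix=reach,
        connections=conn,
        classes=classes,
        ttc_results=results,
        ttc_counts=counts,
        module_sets=module_sets,
        qb=qb,
        enrichment=enrichment,
        interaction=interaction,
        blood=blood_res,
    )


def result_fingerprint(result: PipelineResult) -> dict[str, Any]:
    """Stable summary of a pipeline run for determinism checks."""
    fp: dict[str, Any] = {
        "reach_sum": float(result.reach_matrix.to_numpy().sum()),
        "cutoff": result.connections.cutoff,
        "n_connections": result.connections.n_connections,
        "class_counts": dict(sorted(result.classes.counts.items())),
        "ttc_counts": result.ttc_counts[["pair_id", "count"]]
        .to_records(index=False)
        .tolist(),
        "qb": {k: round(v, 12) for k, v in sorted(result.qb.items())},
        "n_enriched": int(result.enrichment.results.significant.sum()),
    }
    if result.blood is not None:
        fp["blood_stat"] = round(result.blood.statistic, 10)
        fp["blood_p"] = result.blood.p
    return fp
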