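"""End-to-end orchestration: transcriptome -> methylome -> annotation ->
integration -> enrichment -> network, from one config, with logging,
a manifest and a summary funnel table."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, enrichment, integration, io, methylome, network, transcriptome
from .config import PipelineConfig, config_as_dict

log = logging.getLogger("methylink")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineInputs:
    counts: str
    covariates: str
    coverage_files: list[str]
    samples: list[str]
    gtf: str
    islands: str
    gmt: str
    edges: str
    covariate_column: str = "hba1c"


def _setup_logging(out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            h.close()
            log.removeHandler(h)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.setLevel(logging.INFO)
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_all(inputs: PipelineInputs, config: PipelineConfig, out_dir: str) -> dict:
    """Run every stage and write all declared outputs under ``out_dir``.

    Returns a summary dict (also written as summary.tsv) with the
    count funnel: DEGs up/down, DMCs hyper/hypo, DMGs, overlap genes and
    the four concordance categories. A manifest records the config, its
    hash and the seed. Any stage failure aborts with the stage name and
    cause; outputs of completed stages are retained.
    """
    config.validate()
    _setup_logging(out_dir)
    summary: dict = {}

    # ------------------------------------------------------------------ expression
    counts = _stage("transcriptome")(pd.read_csv)(
        inputs.counts, sep="\t", index_col=0
    )
    covariates = pd.read_csv(inputs.covariates, sep="\t", index_col=0)
    log.info("loaded %d genes x %d samples; %d covariate rows",
             *counts.shape, len(covariates))

    @_stage("transcriptome")
    def run_transcriptome():
        cts = transcriptome.drop_zero_genes(counts)
        factors = transcriptome.size_factors(cts)
        clusters = transcriptome.cluster_samples(cts, k=config.k_clusters,
                                                 factors=factors)
        hba1c = covariates[inputs.covariate_column]
        groups = transcriptome.select_extreme_clusters(clusters, hba1c)
        assoc = transcriptome.associate_covariates(groups, covariates)
        selected = [s for s in cts.columns if s in groups]
        de = transcriptome.test_de(cts[selected],
                                   {s: groups[s] for s in selected},
                                   adj_p_threshold=config.de_adj_p_threshold)
        io.write_tsv(clusters.to_frame(), os.path.join(out_dir, "clusters.tsv"),
                     index=True)
        io.write_tsv(assoc, os.path.join(out_dir, "covariate_assoc.tsv"))
        io.write_tsv(de, os.path.join(out_dir, "deg.tsv"), index=True)
        return groups, de

    groups, de = run_transcriptome()
    degs = transcriptome.call_degs(de)
    n1 = sum(1 for g in groups.values() if g == "group1")
    n2 = sum(1 for g in groups.values() if g == "group2")
    summary.update(
        n_samples_group1=n1, n_samples_group2=n2,
        n_genes_tested=len(de), n_degs=len(degs),
        n_degs_up=int((degs["direction"] == "up").sum()),
        n_degs_down=int((degs["direction"] == "down").sum()),
    )
    log.info("groups: %d vs %d samples; %d DEGs (%d up / %d down) of %d genes",
             n1, n2, summary["n_degs"], summary["n_degs_up"],
             summary["n_degs_down"], summary["n_genes_tested"])

    # ------------------------------------------------------------------ methylome
    @_stage("methylome")
    def run_methylome():
        selected = [s for s in inputs.samples if s in groups]
        paths = [p for p, s in zip(inputs.coverage_files, inputs.samples)
                 if s in groups]
        matrix = methylome.read_coverage_files(paths, selected)
        filt_cfg = methylome.MethylationFilterConfig(
            min_coverage=config.min_coverage,
            min_per_group=config.min_per_group,
            excluded_chromosomes=frozenset(config.excluded_chromosomes),
        )
        filtered = methylome.filter_sites(matrix, groups, filt_cfg)
        res = methylome.test_dm(filtered, groups)
        res["q_value"] = methylome.adjust_bh(res["p_value"].values)
        dmcs = methylome.call_dmcs(res, config.meth_diff_threshold,
                                   config.q_threshold)
        io.write_tsv(filtered.sites, os.path.join(out_dir, "sites_filtered.tsv"),
                     index=True)
        io.write_tsv(dmcs, os.path.join(out_dir, "dmc.tsv"), index=True)
        return matrix, filtered, dmcs

    matrix, filtered, dmcs = run_methylome()
    summary.update(
        n_cpgs_total=len(matrix), n_cpgs_filtered=len(filtered),
        n_dmcs=len(dmcs),
        n_dmcs_hyper=int((dmcs["direction"] == "hyper").sum()),
        n_dmcs_hypo=int((dmcs["direction"] == "hypo").sum()),
    )
    log.info("%d CpGs -> %d after filters -> %d DMCs (%d hyper / %d hypo)",
             summary["n_cpgs_total"], summary["n_cpgs_filtered"],
             summary["n_dmcs"], summary["n_dmcs_hyper"], summary["n_dmcs_hypo"])

    # ------------------------------------------------------------------ annotation
    @_stage("annotation")
    def run_annotation():
        genes = io.read_gtf(inputs.gtf)
        islands = io.read_islands_bed(inputs.islands)
        dmc_rows = dmcs.reset_index().rename(columns={"index": "site"})
        dmc_rows["pos"] = dmc_rows["pos"] - 1  # coverage dialect is 1-based
        annotated = annotation.annotate_dmcs(
            dmc_rows[["site", "chrom", "pos", "direction"]], genes, islands,
            promoter_bp=config.promoter_bp, shore_bp=config.shore_bp,
        )
        dmgs = annotation.aggregate_dmgs(annotated)
        io.write_tsv(annotated, os.path.join(out_dir, "dmc_annotated.tsv"))
        io.write_tsv(dmgs, os.path.join(out_dir, "dmg.tsv"))
        return genes, annotated, dmgs

    genes, annotated, dmgs = run_annotation()
    feature_counts = annotated["feature"].value_counts().to_dict()
    context_counts = annotated["cpg_context"].value_counts().to_dict()
    summary.update(
        n_dmgs=len(dmgs),
        n_dmgs_valid_symbol=int(dmgs["valid_symbol"].sum()),
        **{f"n_dmc_{f}": int(feature_counts.get(f, 0))
           for f in annotation.FEATURES},
        **{f"n_dmc_{c}": int(context_counts.get(c, 0))
           for c in annotation.CONTEXTS},
    )
    log.info("%d DMGs (%d with valid symbols); features %s; contexts %s",
             summary["n_dmgs"], summary["n_dmgs_valid_symbol"],
             feature_counts, context_counts)

    # ------------------------------------------------------------------ integration
    symbol_by_id = {g.gene_id: g.symbol for g in genes}

    @_stage("integration")
    def run_integration():
        deg_table = degs.reset_index()
        deg_table["symbol"] = deg_table["gene_id"].map(symbol_by_id)
        deg_table = deg_table.loc[deg_table["symbol"].astype(bool)]
        records = integration.integrate(deg_table, dmgs)
        io.write_tsv(records, os.path.join(out_dir, "overlap.tsv"))
        return deg_table, records

    deg_table, records = run_integration()
    cats = integration.category_counts(records)
    summary.update(
        n_overlap_genes=records["gene"].nunique(),
        n_overlap_pairs=len(records),
        **{f"n_{k.lower().replace('-', '_')}": v for k, v in cats.items()},
    )
    log.info("overlap: %d genes, %d (gene, direction) pairs, categories %s",
             summary["n_overlap_genes"], summary["n_overlap_pairs"], cats)

    # ------------------------------------------------------------------ enrichment
    @_stage("enrichment")
    def run_enrichment():
        collection = io.read_gmt(inputs.gmt)
        deg_universe = sorted(
            {symbol_by_id.get(g, "") for g in de.index} - {""}
        )
        dmg_universe = sorted(
            set(dmgs.loc[dmgs["valid_symbol"], "symbol"]) | set(deg_universe)
        )
        deg_query = sorted(set(deg_table["symbol"]))
        dmg_query = sorted(set(dmgs.loc[dmgs["valid_symbol"], "symbol"]))
        res_deg = enrichment.enrich(deg_query, collection, deg_universe,
                                    cutoff=config.enrich_cutoff,
                                    mode=config.enrich_mode_deg)
        res_dmg = enrichment.enrich(dmg_query, collection, dmg_universe,
                                    cutoff=config.enrich_cutoff,
                                    mode=config.enrich_mode_dmg)
        io.write_tsv(res_deg, os.path.join(out_dir, "enrichment_deg.tsv"))
        io.write_tsv(res_dmg, os.path.join(out_dir, "enrichment_dmg.tsv"))
        io.write_tsv(enrichment.dotplot_table(res_deg),
                     os.path.join(out_dir, "dotplot_deg.tsv"))
        clusters, kappa_table = enrichment.cluster_terms(
            res_deg, collection, deg_query,
            kappa_threshold=config.kappa_threshold,
            min_terms=config.min_cluster_terms,
        )
        pd.DataFrame(
            [(c["cluster"], c["size"], ";".join(c["terms"])) for c in clusters],
            columns=["cluster", "size", "terms"],
        ).to_csv(os.path.join(out_dir, "term_clusters_deg.tsv"), sep="\t",
                 index=False)
        same, opposite = integration.split_by_concordance(records)
        for name, genes_ in (("same", same), ("opposite", opposite)):
            if genes_:
                res = enrichment.enrich(sorted(genes_), collection, dmg_universe,
                                        cutoff=config.enrich_cutoff,
                                        mode=config.enrich_mode_dmg)
            else:
                res = pd.DataFrame()
            io.write_tsv(res, os.path.join(out_dir, f"enrichment_{name}.tsv"))
        return res_deg, res_dmg, clusters, collection, deg_universe

    res_deg, res_dmg, term_clusters, collection, deg_universe = run_enrichment()
    summary.update(
        n_enriched_terms_deg=int(res_deg["significant"].sum())
        if len(res_deg) else 0,
        n_enriched_terms_dmg=int(res_dmg["significant"].sum())
        if len(res_dmg) else 0,
        n_term_clusters_deg=len(term_clusters),
    )

    # ------------------------------------------------------------------ network
    @_stage("network")
    def run_network():
        edges = io.read_edge_table(inputs.edges)
        g = network.build_network(set(deg_table["symbol"]), edges,
                                  config.network_score_threshold)
        g = network.overlay_methylation(g, dmgs)
        subnets = network.major_subnetworks(g, config.network_min_subnetwork)
        nodes_df, edges_df = network.network_tables(g)
        io.write_tsv(nodes_df, os.path.join(out_dir, "network_nodes.tsv"))
        io.write_tsv(edges_df, os.path.join(out_dir, "network_edges.tsv"))
        import networkx as nx
        nx.write_graphml(g, os.path.join(out_dir, "network.graphml"))
        sub_rows = []
        for i, members in enumerate(subnets, 1):
            res = enrichment.enrich(
                sorted(set(members) & set(deg_universe)), collection,
                deg_universe, cutoff=config.enrich_cutoff,
                mode=config.enrich_mode_deg,
            )
            for rec in res.loc[res["significant"]].itertuples(index=False):
                sub_rows.append((f"subnet{i}", len(members), rec.term,
                                 rec.name, rec.p_value, rec.adjusted_p))
        pd.DataFrame(
            sub_rows, columns=["subnetwork", "size", "term", "name",
                               "p_value", "adjusted_p"],
        ).to_csv(os.path.join(out_dir, "subnetwork_enrichment.tsv"),
                 sep="\t", index=False)
        return g, subnets

    g, subnets = run_network()
    summary.update(
        n_network_nodes=g.number_of_nodes(),
        n_network_edges=g.number_of_edges(),
        n_major_subnetworks=len(subnets),
    )
    log.info("network: %d nodes, %d edges, %d major subnetworks",
             summary["n_network_nodes"], summary["n_network_edges"],
             summary["n_major_subnetworks"])

    # sanity: the funnel must be internally consistent
    assert summary["n_degs_up"] + summary["n_degs_down"] == summary["n_degs"]
    assert summary["n_dmcs_hyper"] + summary["n_dmcs_hypo"] == summary["n_dmcs"]
    cat_sum = sum(cats.values())
    assert cat_sum == summary["n_overlap_pairs"]

    summary_df = pd.DataFrame(sorted(summary.items()),
                              columns=["metric", "value"])
    io.write_tsv(summary_df, os.path.join(out_dir, "summary.tsv"))
    cfg_dict = config_as_dict(config)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "inputs": {k: v for k, v in vars(inputs).items()
                   if not isinstance(v, list)},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def run_demo(out_dir: str, seed: int = 0, sim_config=None,
             config: PipelineConfig | None = None) -> dict:
    """Simulate a study under ``out_dir``/sim and run the full pipeline on
    it under ``out_dir``/run. The synthetic study plants two sample
    groups, so the demo cuts the sample dendrogram at k = 2."""
    from .config import SimulationConfig
    from .simulate import simulate_study

    sim_config = sim_config or SimulationConfig(seed=seed)
    paths = simulate_study(sim_config, os.path.join(out_dir, "sim"))
    config = config or PipelineConfig(seed=seed, k_clusters=2)
    inputs = PipelineInputs(
        counts=paths["counts"], covariates=paths["covariates"],
        coverage_files=paths["coverage_files"], samples=paths["samples"],
        gtf=paths["gtf"], islands=paths["islands"], gmt=paths["gmt"],
        edges=paths["edges"],
    )
    return run_all(inputs, config, os.path.join(out_dir, "run"))
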