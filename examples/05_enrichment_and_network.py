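"""Hypergeometric enrichment with kappa clustering, and the DEG network.

A query list is tested against a GMT collection within a stated gene
universe; significant terms are grouped by Cohen's-kappa membership
agreement (kappa > 0.5, >= 5 terms per cluster). DEGs are then wired
into an interaction network at score > 0.9 with methylation overlaid.
"""

import methylink as ml
from methylink.enrichment import dotplot_table
from methylink.simulate import (sample_ids, simulate_gene_sets,
                                simulate_interactions)
from methylink.transcriptome import call_degs

cfg = ml.SimulationConfig(seed=3)
genes, islands = ml.generate_annotation(cfg)
counts, covariates, truth = ml.simulate_expression(cfg, genes)
_, groups = sample_ids(cfg)
collection = simulate_gene_sets(genes, cfg, truth)

symbol = {g.gene_id: g.symbol for g in genes}
de = ml.test_de(counts, groups)
universe = sorted({symbol.get(g, "") for g in de.index} - {""})
degs = call_degs(de)
query = sorted({symbol.get(g, "") for g in degs.index} - {""})

res = ml.enrich(query, collection, universe, cutoff=0.05, mode="adjusted")
print(dotplot_table(res, top=5).round(3).to_string(index=False))
clusters, _ = ml.cluster_terms(res.loc[res["significant"]], collection, query)
print(f"{int(res['significant'].sum())} significant terms, "
      f"{len(clusters)} kappa clusters")

edges = simulate_interactions(genes, cfg, truth)
g = ml.build_network(query, edges, score_threshold=0.9)
subnets = ml.major_subnetworks(g)
print(f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges, "
      f"major subnetworks of sizes {[len(c) for c in subnets]}")
# The rich factor is k/K: the fraction of a term's genes hit by the
# query; the planted term families should dominate the top of the table.
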