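"""Map DMCs to nearest-TSS genes and cross them with DEGs.

Each DMC is assigned to the gene with the closest transcript start site,
classified by genomic feature and CpG-island context, rolled up to DMGs,
and the DMG/DEG intersection is split into the four concordance
categories (Hypo-Down, Hypo-Up, Hyper-Down, Hyper-Up).
"""

import methylink as ml
from methylink.integration import category_counts
from methylink.simulate import sample_ids
from methylink.transcriptome import call_degs

cfg = ml.SimulationConfig(seed=8)  # 21 vs 32 samples, 200 genes, 2000 CpGs
genes, islands = ml.generate_annotation(cfg)
meth, unmeth, sites, _ = ml.simulate_methylation(cfg, genes, islands)
counts, covariates, _ = ml.simulate_expression(cfg, genes)
_, groups = sample_ids(cfg)

res = ml.test_dm(ml.filter_sites(ml.CpGCountMatrix(meth, unmeth, sites), groups),
                 groups)
res["q_value"] = ml.adjust_bh(res["p_value"].values)
dmcs = ml.call_dmcs(res).reset_index()
dmcs["pos"] = dmcs["pos"] - 1  # coverage files are 1-based

annotated = ml.annotate_dmcs(dmcs[["site", "chrom", "pos", "direction"]],
                             genes, islands)
dmgs = ml.aggregate_dmgs(annotated)
print(annotated["feature"].value_counts().to_dict())
print(annotated["cpg_context"].value_counts().to_dict())

deg = call_degs(ml.test_de(counts, groups)).reset_index()
deg["symbol"] = deg["gene_id"].map({g.gene_id: g.symbol for g in genes})
deg = deg.loc[deg["symbol"].astype(bool)]
records = ml.integrate(deg, dmgs)
print(f"{records['gene'].nunique()} shared genes, "
      f"{len(records)} (gene, methylation-direction) pairs")
print(category_counts(records))
# Hypo-Up and Hyper-Down pairs are discordant (methylation and expression
# move oppositely); Hypo-Down and Hyper-Up are concordant.
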