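"""One-command demo: simulate a study and run every stage end to end.

Equivalent to `methylink simulate` followed by `methylink all`; prints
the summary funnel the pipeline writes to summary.tsv.
"""

import tempfile

import methylink as ml

with tempfile.TemporaryDirectory() as out:
    summary = ml.run_demo(out, seed=1)

for key in ("n_samples_group1", "n_samples_group2", "n_genes_tested",
            "n_degs", "n_degs_up", "n_degs_down", "n_cpgs_filtered",
            "n_dmcs", "n_dmcs_hyper", "n_dmcs_hypo", "n_dmgs",
            "n_overlap_genes", "n_overlap_pairs", "n_hypo_down", "n_hypo_up",
            "n_hyper_down", "n_hyper_up", "n_network_nodes",
            "n_major_subnetworks"):
    print(f"{key:22s} {summary[key]}")
# The funnel is the synthetic analogue of the study's headline counts:
# DEGs split into up/down, DMCs into hyper/hypo, their gene-level overlap
# into the four concordance categories (whose counts sum to the number of
# (gene, methylation-direction) pairs, not unique genes).
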