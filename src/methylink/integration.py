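"""Four-way methylation x expression concordance integration.

Genes shared between the DMG and DEG sets are classified by crossing
the methylation direction (hyper/hypo, group 1 vs group 2) with the
expression direction (up/down): Hypo-Down, Hypo-Up, Hyper-Down and
Hyper-Up. Hypo-Up and Hyper-Down are "opposite-direction" (discordant)
changes, Hypo-Down and Hyper-Up "same-direction" (concordant). A gene
carrying both hyper- and hypomethylated CpGs yields one record per
(gene, methylation-direction) pair, so category counts may exceed the
number of unique shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORY = {
    ("hypo", "down"): "Hypo-Down",
    ("hypo", "up"): "Hypo-Up",
    ("hyper", "down"): "Hyper-Down",
    ("hyper", "up"): "Hyper-Up",
}
OPPOSITE = {"Hypo-Up", "Hyper-Down"}


@dataclass
class ConcordanceRecord:
    gene: str
    meth_direction: str
    expr_direction: str
    category: str
    concordance: str  # same-direction | opposite-direction
    dmc_ids: tuple = ()


def overlap_genes(deg_genes, dmg_genes) -> set[str]:
    """Exact intersection of DEG and DMG gene-symbol sets."""
    return set(deg_genes) & set(dmg_genes)


def categorize(gene: str, meth_directions, expr_direction: str,
               dmc_ids=()) -> list[ConcordanceRecord]:
    """One record per (gene, methylation-direction) pair."""
    if expr_direction not in ("up", "down"):
        raise ValueError(f"unknown expression direction {expr_direction!r}")
    records = []
    for mdir in sorted(set(meth_directions)):
        if mdir not in ("hyper", "hypo"):
            raise ValueError(f"unknown methylation direction {mdir!r}")
        cat = CATEGORY[(mdir, expr_direction)]
        records.append(
            ConcordanceRecord(
                gene=gene, meth_direction=mdir, expr_direction=expr_direction,
                category=cat,
                concordance=("opposite-direction" if cat in OPPOSITE
                             else "same-direction"),
                dmc_ids=tuple(dmc_ids),
            )
        )
    return records


def integrate(deg_table: pd.DataFrame, dmg_table: pd.DataFrame) -> pd.DataFrame:
    """Classify every gene shared between a DEG table and a DMG table.

    ``deg_table`` needs columns (symbol, direction); ``dmg_table`` needs
    (symbol, directions, dmc_ids, valid_symbol) as produced by
    :func:`methylink.annotation.aggregate_dmgs`.
    """
    dmg = dmg_table.loc[dmg_table["valid_symbol"]]
    deg_dir = dict(zip(deg_table["symbol"], deg_table["direction"]))
    shared = overlap_genes(deg_dir, dmg["symbol"])
    rows = []
    for rec in dmg.itertuples(index=False):
        if rec.symbol not in shared:
            continue
        for r in categorize(rec.symbol, rec.directions.split(","),
                            deg_dir[rec.symbol], rec.dmc_ids.split(",")):
            rows.append(
                dict(gene=r.gene, meth_direction=r.meth_direction,
                     expr_direction=r.expr_direction, category=r.category,
                     concordance=r.concordance, n_dmcs=len(r.dmc_ids),
                     dmc_ids=",".join(r.dmc_ids))
            )
    out = pd.DataFrame(
        rows, columns=["gene", "meth_direction", "expr_direction",
                       "category", "concordance", "n_dmcs", "dmc_ids"]
    )
    return out.sort_values(["category", "gene"]).reset_index(drop=True)


def split_by_concordance(records: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Gene sets with same-direction and opposite-direction changes.

    A gene with both methylation directions appears in both sets.
    """
    same = set(records.loc[records["concordance"] == "same-direction", "gene"])
    opposite = set(records.loc[records["concordance"] == "opposite-direction", "gene"])
    return same, opposite


def category_counts(records: pd.DataFrame) -> dict[str, int]:
    counts = {cat: 0 for cat in CATEGORY.values()}
    counts.update(records["category"].value_counts().to_dict())
    return counts
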