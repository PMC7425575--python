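"""Score-filtered interaction network over DEGs with methylation overlay.

The network is the subgraph of a supplied interaction edge table induced
on the DEG genes, keeping edges whose confidence score strictly exceeds
the threshold (default 0.9, the highest-confidence convention) and
dropping singletons not connected to another gene. Nodes are coloured by
the methylation direction of their DMG record: hyper, hypo, both, or
none. Connected components ordered by size are the subnetworks handed to
functional enrichment.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


class NetworkError(ValueError):
    pass


def _normalise_scores(scores: pd.Series) -> pd.Series:
    # STRING exports use either a 0-1 or a 0-1000 combined-score scale
    if scores.max() > 1.0:
        return scores / 1000.0
    return scores


def build_network(
    deg_genes,
    edges: pd.DataFrame,
    score_threshold: float = 0.9,
) -> nx.Graph:
    """Induce the DEG subgraph at score > threshold and prune singletons."""
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(edges.columns):
        raise NetworkError(f"edge table needs columns {sorted(required)}")
    deg_genes = set(deg_genes)
    scores = _normalise_scores(edges["score"].astype(float))
    g = nx.Graph()
    for (a, b), score in zip(edges[["gene_a", "gene_b"]].itertuples(index=False),
                             scores):
        if a == b:
            continue
        if score <= score_threshold:  # strict: score == threshold excluded
            continue
        if a in deg_genes and b in deg_genes:
            prev = g.get_edge_data(a, b)
            if prev is None or score > prev["score"]:
                g.add_edge(a, b, score=float(score))
    return prune_singletons(g)


def prune_singletons(g: nx.Graph) -> nx.Graph:
    """Drop nodes without any neighbour; idempotent."""
    keep = [n for n in g.nodes if g.degree(n) > 0]
    return g.subgraph(keep).copy()


def overlay_methylation(g: nx.Graph, dmg_table: pd.DataFrame) -> nx.Graph:
    """Label each node hyper/hypo/both from its DMG direction set, none
    otherwise. ``dmg_table`` as from annotation.aggregate_dmgs."""
    directions = {
        rec.symbol: set(rec.directions.split(","))
        for rec in dmg_table.itertuples(index=False)
        if rec.valid_symbol
    }
    for node in g.nodes:
        dirs = directions.get(node)
        if not dirs:
            label = "none"
        elif dirs == {"hyper"}:
            label = "hyper"
        elif dirs == {"hypo"}:
            label = "hypo"
        else:
            label = "both"
        g.nodes[node]["methylation"] = label
    return g


def major_subnetworks(g: nx.Graph, min_size: int = 3) -> list[list[str]]:
    """Connected components with >= min_size nodes, largest first;
    ties broken by the lexicographically smallest member gene."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0] if c else ""))
    return [c for c in comps if len(c) >= min_size]


def network_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        [(n, g.nodes[n].get("methylation", "none"), g.degree(n))
         for n in sorted(g.nodes)],
        columns=["gene", "methylation", "degree"],
    )
    edges = pd.DataFrame(
        [(min(a, b), max(a, b), d["score"]) for a, b, d in g.edges(data=True)],
        columns=["gene_a", "gene_b", "score"],
    ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return nodes, edges
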