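"""Hypergeometric over-representation analysis with kappa term clustering.

For a query gene list against a GMT collection within a stated universe
of N genes, a term with K members of which k are in the n-gene query is
scored with the upper-tail hypergeometric probability P(X >= k).
Benjamini-Hochberg correction runs across the tested terms of a
collection; the significance flag uses either the adjusted (DEG-style
runs) or the nominal (DMG-style runs) p at the configured cutoff. The
rich factor k/K measures the coverage of a term by the query.

Redundant significant terms are grouped by Cohen's kappa agreement of
their membership vectors over the query genes: terms sharing kappa
strictly above the threshold are linked, and connected components with
at least ``min_terms`` members become term clusters.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .methylome import adjust_bh


class EnrichmentError(ValueError):
    pass


def hypergeom_test(query, term, universe) -> float:
    """Upper-tail hypergeometric p for the query/term overlap.

    The term is intersected with the universe before testing; query
    genes outside the universe raise an error listing the offenders.
    """
    query, universe = set(query), set(universe)
    outside = sorted(query - universe)
    if outside:
        raise EnrichmentError(f"query genes outside the universe: {outside[:10]}")
    term = set(term) & universe
    N, K, n = len(universe), len(term), len(query)
    k = len(query & term)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    collection: dict[str, dict],
    universe,
    cutoff: float = 0.05,
    mode: str = "adjusted",
) -> pd.DataFrame:
    """Test every term of a collection against a query gene list.

    Returns one row per term with k >= 1 hits, sorted by p, with BH
    adjustment across all tested terms and a ``significant`` flag at the
    configured cutoff in either "adjusted" or "nominal" mode.
    """
    if mode not in ("adjusted", "nominal"):
        raise EnrichmentError(f"mode must be 'adjusted' or 'nominal', got {mode!r}")
    query, universe = set(query), set(universe)
    outside = sorted(query - universe)
    if outside:
        raise EnrichmentError(f"query genes outside the universe: {outside[:10]}")
    if not query:
        warnings.warn("empty query gene list; no enrichment computed")
    N, n = len(universe), len(query)
    rows = []
    for term_id, rec in collection.items():
        members = set(rec["genes"]) & universe
        if not members:
            continue
        hits = sorted(query & members)
        K, k = len(members), len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(term=term_id, name=rec.get("name", term_id), k=k, n=n, K=K,
                 N=N, p_value=p, rich_factor=(k / K if K else np.nan),
                 hits=",".join(hits))
        )
    df = pd.DataFrame(
        rows, columns=["term", "name", "k", "n", "K", "N", "p_value",
                       "rich_factor", "hits"]
    )
    if df.empty:
        df["adjusted_p"] = df["significant"] = []
        return df
    df["adjusted_p"] = adjust_bh(df["p_value"].values)
    df = df.loc[df["k"] >= 1].copy()
    basis = df["adjusted_p"] if mode == "adjusted" else df["p_value"]
    df["significant"] = basis < cutoff
    return df.sort_values(["p_value", "term"]).reset_index(drop=True)


def dotplot_table(results: pd.DataFrame, top: int = 20) -> pd.DataFrame:
    """Top-``top`` terms by p with the dot-plot quantities."""
    df = results.nsmallest(top, "p_value").copy()
    df["neg_log10_p"] = -np.log10(np.clip(df["p_value"], 1e-300, None))
    return df[["term", "name", "rich_factor", "k", "neg_log10_p"]]


def kappa(term_a, term_b, reference) -> float:
    """Cohen's kappa agreement of two term memberships over a reference
    gene list: (po - pe) / (1 - pe); 1.0 when the memberships agree
    perfectly (including the degenerate all-in/all-out case)."""
    reference = list(dict.fromkeys(reference))
    if not reference:
        raise EnrichmentError("reference gene list must be non-empty")
    a = np.array([g in set(term_a) for g in reference])
    b = np.array([g in set(term_b) for g in reference])
    n = len(reference)
    po = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def cluster_terms(
    results: pd.DataFrame,
    collection: dict[str, dict],
    reference,
    kappa_threshold: float = 0.5,
    min_terms: int = 5,
) -> tuple[list[dict], pd.DataFrame]:
    """Single-linkage term clusters on the kappa > threshold graph.

    Considers the significant terms of ``results``; connected components
    with >= ``min_terms`` terms become clusters, smaller components are
    reported unclustered. Returns (clusters, pairwise-kappa long table).
    """
    terms = list(results.loc[results.get("significant", True), "term"]) \
        if "significant" in results.columns else list(results["term"])
    g = nx.Graph()
    g.add_nodes_from(terms)
    pairs = []
    for a, b in combinations(terms, 2):
        kab = kappa(collection[a]["genes"], collection[b]["genes"], reference)
        pairs.append((a, b, kab))
        if kab > kappa_threshold:
            g.add_edge(a, b)
    clusters = []
    cluster_id = 0
    for comp in sorted(nx.connected_components(g),
                       key=lambda c: (-len(c), min(c))):
        members = sorted(comp)
        if len(members) >= min_terms:
            cluster_id += 1
            clusters.append(dict(cluster=f"C{cluster_id}", terms=members,
                                 size=len(members)))
    kappa_table = pd.DataFrame(pairs, columns=["term_a", "term_b", "kappa"])
    return clusters, kappa_table
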