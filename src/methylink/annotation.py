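"""Gene-level annotation of differentially methylated CpGs.

Each DMC is mapped to the gene whose transcript start site (TSS) is
closest on the same chromosome, then classified by genomic feature
(promoter / exon / intron / intergenic) and by CpG-island context
(island / shore / other). Genes collecting at least one DMC become
differentially methylated genes (DMGs); a gene may carry both hyper-
and hypomethylated CpGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FEATURES = ("promoter", "exon", "intron", "intergenic")
CONTEXTS = ("island", "shore", "other")


@dataclass
class GeneModel:
    """A single-transcript gene model in 0-based half-open coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty gene span")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        """TSS position: gene start on '+', (end - 1) on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def has_valid_symbol(self) -> bool:
        return bool(self.symbol)


class CpGIslandSet:
    """CpG-island intervals (0-based half-open) with fast point queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self.intervals = sorted(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self._edges: dict[str, np.ndarray] = {
            chrom: np.sort(
                np.array(
                    [b for iv in tree for b in (iv.begin, iv.end - 1)], dtype=int
                )
            )
            for chrom, tree in self._trees.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    def distance_to_edge(self, chrom: str, pos: int) -> float:
        """Distance in bp from pos to the nearest island boundary base."""
        edges = self._edges.get(chrom)
        if edges is None or len(edges) == 0:
            return float("inf")
        i = np.searchsorted(edges, pos)
        cands = edges[max(i - 1, 0):i + 1]
        return float(np.min(np.abs(cands - pos)))


# ---------------------------------------------------------------------------
# nearest-TSS assignment
# ---------------------------------------------------------------------------

def nearest_tss_gene(
    chrom: str, pos: int, genes: Sequence[GeneModel]
) -> tuple[GeneModel | None, int | None]:
    """Assign a position to the gene with the closest TSS on its chromosome.

    Ties on |TSS - pos| are broken by lexicographically smallest gene id.
    The returned distance is signed by gene orientation: negative means
    the site lies upstream of the TSS. Returns ``(None, None)`` with a
    warning when the chromosome carries no gene.
    """
    best: GeneModel | None = None
    best_abs = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(g.tss - pos)
        if best is None or d < best_abs or (d == best_abs and g.gene_id < best.gene_id):
            best, best_abs = g, d
    if best is None:
        warnings.warn(f"no gene on chromosome {chrom}; site {pos} left unmapped")
        return None, None
    signed = pos - best.tss if best.strand == "+" else best.tss - pos
    return best, int(signed)


class TssIndex:
    """Sorted per-chromosome TSS arrays for O(log n) nearest-gene queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            # sort by (tss, gene_id) so equidistant ties resolve to the
            # lexicographically smallest id deterministically
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (np.array([g.tss for g in gs]), gs)

    def nearest(self, chrom: str, pos: int) -> tuple[GeneModel | None, int | None]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            warnings.warn(f"no gene on chromosome {chrom}; site {pos} left unmapped")
            return None, None
        tss, gs = entry
        i = int(np.searchsorted(tss, pos))
        cands = [gs[j] for j in range(max(i - 1, 0), min(i + 1, len(gs)))]
        # include all genes sharing the candidate TSS values for tie-breaks
        dists = {abs(g.tss - pos) for g in cands}
        dmin = min(dists)
        tied = [g for (t, g) in zip(tss, gs) if abs(t - pos) == dmin]
        best = min(tied, key=lambda g: g.gene_id)
        signed = pos - best.tss if best.strand == "+" else best.tss - pos
        return best, int(signed)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_feature(pos: int, gene: GeneModel, promoter_bp: int = 5000) -> str:
    """Classify a site against its assigned gene.

    Promoter: within ``promoter_bp`` strictly upstream of the TSS (strand
    aware, inclusive bound) and not inside the gene body. Otherwise exon
    if inside any exon, intron if inside the transcript span, else
    intergenic. Precedence promoter > exon > intron > intergenic.
    """
    upstream = gene.tss - pos if gene.strand == "+" else pos - gene.tss
    in_body = gene.start <= pos < gene.end
    if 0 < upstream <= promoter_bp and not in_body:
        return "promoter"
    if any(s <= pos < e for s, e in gene.exons):
        return "exon"
    if in_body:
        return "intron"
    return "intergenic"


def classify_cpg_context(
    chrom: str, pos: int, islands: CpGIslandSet, shore_bp: int = 2000
) -> str:
    """Island if inside an island; shore if within ``shore_bp`` of an
    island boundary; otherwise other."""
    if islands.contains(chrom, pos):
        return "island"
    if islands.distance_to_edge(chrom, pos) <= shore_bp:
        return "shore"
    return "other"


# ---------------------------------------------------------------------------
# DMC -> gene annotation and DMG aggregation
# ---------------------------------------------------------------------------

def annotate_dmcs(
    dmcs: pd.DataFrame,
    genes: Sequence[GeneModel],
    islands: CpGIslandSet,
    promoter_bp: int = 5000,
    shore_bp: int = 2000,
) -> pd.DataFrame:
    """Annotate each DMC row (chrom, pos, direction) with its nearest gene,
    signed TSS distance, genomic feature and CpG-island context.

    Positions are 0-based here; callers converting from coverage-file
    coordinates subtract one first.
    """
    index = TssIndex(genes)
    rows = []
    for rec in dmcs.itertuples(index=False):
        gene, signed = index.nearest(rec.chrom, rec.pos)
        if gene is None:
            rows.append(
                dict(site=rec.site, chrom=rec.chrom, pos=rec.pos,
                     direction=rec.direction, gene_id="", symbol="",
                     tss_distance=np.nan, feature="unmapped",
                     cpg_context=classify_cpg_context(rec.chrom, rec.pos,
                                                      islands, shore_bp))
            )
            continue
        rows.append(
            dict(
                site=rec.site, chrom=rec.chrom, pos=rec.pos,
                direction=rec.direction, gene_id=gene.gene_id,
                symbol=gene.symbol, tss_distance=signed,
                feature=classify_feature(rec.pos, gene, promoter_bp),
                cpg_context=classify_cpg_context(rec.chrom, rec.pos,
                                                 islands, shore_bp),
            )
        )
    return pd.DataFrame(
        rows, columns=["site", "chrom", "pos", "direction", "gene_id",
                       "symbol", "tss_distance", "feature", "cpg_context"]
    )


def aggregate_dmgs(annotated: pd.DataFrame) -> pd.DataFrame:
    """Roll annotated DMCs up to one row per gene.

    The per-gene direction set is the union over its DMCs, so a gene may
    be both hyper- and hypomethylated. Genes without a valid official
    symbol are flagged and excluded from downstream overlap analysis.
    """
    mapped = annotated[annotated["gene_id"] != ""]
    rows = []
    for gene_id, grp in mapped.groupby("gene_id", sort=True):
        directions = sorted(set(grp["direction"]))
        rows.append(
            dict(
                gene_id=gene_id,
                symbol=grp["symbol"].iloc[0],
                n_dmcs=len(grp),
                dmc_ids=",".join(grp["site"]),
                directions=",".join(directions),
                valid_symbol=bool(grp["symbol"].iloc[0]),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "n_dmcs", "dmc_ids",
                       "directions", "valid_symbol"]
    )
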