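"""Readers and writers for the on-disk formats the pipeline exchanges.

Coordinate conventions: internal coordinates are 0-based half-open;
GTF (1-based inclusive), Bismark coverage files (1-based positions) and
BED (0-based half-open) are converted at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .annotation import CpGIslandSet, GeneModel


class ParseError(ValueError):
    """A malformed row in an input file, reported with file and line."""


# ---------------------------------------------------------------------------
# Bismark-style coverage files
# chromosome, start (1-based), end (inclusive), methylation %, #C, #T
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]


def read_coverage_file(path) -> pd.DataFrame:
    """Read one Bismark-dialect coverage TSV into a per-site count table.

    The percentage column is ignored in favour of recomputation from the
    counts downstream. Duplicate sites or malformed rows raise
    :class:`ParseError` naming the file and line.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=COVERAGE_COLUMNS, comment="#",
            dtype={"chrom": str},
        )
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse coverage file: {exc}") from exc
    if df.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 tab-separated columns")
    for col in ("start", "end", "count_meth", "count_unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: line {line}: column '{col}' must be a non-negative integer"
            )
        df[col] = numeric.astype(int)
    dup = df.duplicated(subset=["chrom", "start"])
    if dup.any():
        line = int(dup.idxmax()) + 1
        raise ParseError(f"{path}: line {line}: duplicate site within one file")
    return df


def write_coverage_file(df: pd.DataFrame, path) -> None:
    """Write a coverage table (columns as in :data:`COVERAGE_COLUMNS`)."""
    out = df.copy()
    out["meth_pct"] = out["meth_pct"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene/transcript/exon features, converting to 1-based inclusive."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            if g.symbol:
                attrs += f' gene_name "{g.symbol}";'
            base = f"{g.chrom}\tmethylink\t%s\t%d\t%d\t.\t{g.strand}\t.\t"
            fh.write(base % ("gene", g.start + 1, g.end) + attrs + "\n")
            tx_attrs = attrs + f' transcript_id "{g.gene_id}.t1";'
            fh.write(base % ("transcript", g.start + 1, g.end) + tx_attrs + "\n")
            for s, e in g.exons:
                fh.write(base % ("exon", s + 1, e) + tx_attrs + "\n")


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF via gffutils (in-memory DB).

    One TSS per gene: the most upstream transcript start on the gene's
    strand. Exons are the union over transcripts.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            {(e.start - 1, e.end) for e in db.children(g, featuretype="exon")}
        )
        name = g.attributes.get("gene_name", [""])
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=name[0] if name else "",
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons or [(g.start - 1, g.end)],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# BED6 CpG islands (0-based half-open, as BED is)
# ---------------------------------------------------------------------------

def write_islands_bed(islands: CpGIslandSet, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(islands.intervals):
            fh.write(f"{chrom}\t{start}\t{end}\tCpGi_{i + 1}\t0\t+\n")


def read_islands_bed(path) -> CpGIslandSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    bad = (df["end"] <= df["start"]) | (df["start"] < 0)
    if bad.any():
        raise ParseError(f"{path}: line {int(bad.idxmax()) + 1}: invalid interval")
    return CpGIslandSet(list(df.itertuples(index=False, name=None)))


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file: term id, description, then member genes.

    Returns ``{term_id: {"name": description, "genes": set}}``.
    """
    collection: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need term, description, >=1 gene"
                )
            term, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in collection:
                raise ParseError(f"{path}: line {lineno}: duplicate term id {term!r}")
            if not genes:
                raise ParseError(f"{path}: line {lineno}: empty member set")
            collection[term] = {"name": name, "genes": set(genes)}
    return collection


def write_gmt(collection: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for term, rec in collection.items():
            genes = "\t".join(sorted(rec["genes"]))
            fh.write(f"{term}\t{rec.get('name', term)}\t{genes}\n")


# ---------------------------------------------------------------------------
# Interaction edge tables
# ---------------------------------------------------------------------------

def read_edge_table(path) -> pd.DataFrame:
    """Read a STRING-export-style edge table (gene_a, gene_b, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: edge table needs columns {sorted(required)}")
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        line = int(score.isna().idxmax()) + 2  # header line
        raise ParseError(f"{path}: line {line}: non-numeric score")
    df["score"] = score
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
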