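"""Synthetic two-group methylome + transcriptome study generator.

Emulates the statistical structure the downstream stages assume: a toy
genome with non-overlapping gene models and CpG islands; per-CpG
methylated/unmethylated counts with negative-binomial sampling depth and
beta-binomial overdispersion, with a planted group shift at a chosen
fraction of sites; negative-binomial gene counts with log-normal size
factors and planted fold changes; and a clinical covariate table whose
HbA1c-like value drives group membership deterministically (group =
side of the threshold midway between the two group means). Every output
is reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .annotation import CpGIslandSet, GeneModel
from .config import ConfigError, SimulationConfig


class SimulationSizeError(ValueError):
    """A chromosome is too small for the requested features."""


@dataclass
class GroundTruth:
    """Planted differential signal for parameter-recovery checks."""

    dm_sites: set = field(default_factory=set)
    dm_direction: dict = field(default_factory=dict)
    de_genes: set = field(default_factory=set)
    de_direction: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.dm_sites != set(self.dm_direction):
            raise ValueError("dm_sites and dm_direction disagree")
        if self.de_genes != set(self.de_direction):
            raise ValueError("de_genes and de_direction disagree")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _place_intervals(rng, chrom_len: int, lengths: np.ndarray, min_gap: int):
    """Place non-overlapping intervals of given lengths on [0, chrom_len)
    with random gaps; raises SimulationSizeError if they do not fit."""
    n = len(lengths)
    needed = int(lengths.sum()) + (n + 1) * min_gap
    if needed > chrom_len:
        raise SimulationSizeError(
            f"chromosome of {chrom_len} bp too small for {n} features "
            f"needing {needed} bp"
        )
    slack = chrom_len - needed
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts, cursor = [], 0
    for i, length in enumerate(lengths):
        cursor += min_gap + int(extra[i])
        starts.append(cursor)
        cursor += int(length)
    return np.array(starts, dtype=int)


def _split_counts(total: int, parts: int, rng) -> list[int]:
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False)) \
        if parts > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def generate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], CpGIslandSet]:
    """Toy gene models and CpG islands on the configured chromosomes.

    Gene bodies are pairwise non-overlapping (hence non-overlapping per
    strand), each has 1-5 exons, and the TSS is the strand-appropriate
    gene end. About 5% of genes get no official symbol to exercise the
    downstream valid-symbol filter. Islands are placed independently.
    """
    rng = _streams(config.seed, 5)[0]
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    # genes allocated proportionally to chromosome length
    alloc = np.floor(sizes / sizes.sum() * config.n_genes).astype(int)
    for i in np.argsort(-sizes):
        if alloc.sum() >= config.n_genes:
            break
        alloc[i] += config.n_genes - alloc.sum()
    genes: list[GeneModel] = []
    gene_no = 0
    for chrom, n_c in zip(chroms, alloc):
        if n_c == 0:
            continue
        chrom_len = config.chrom_sizes[chrom]
        max_len = max(min(15000, (chrom_len - 200 * (n_c + 1)) // max(n_c, 1)), 2000)
        lengths = rng.integers(2000, max_len + 1, size=n_c)
        starts = _place_intervals(rng, chrom_len, lengths, min_gap=200)
        for start, length in zip(starts, lengths):
            gene_no += 1
            gene_id = f"G{gene_no:04d}"
            symbol = "" if rng.random() < 0.05 else f"GENE{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            end = int(start + length)
            n_exons = int(rng.integers(1, 6))
            segs = 2 * n_exons - 1
            if length < segs * 100:
                n_exons, segs = 1, 1
            widths = np.array(_split_counts(int(length) - segs * 50, segs, rng)) + 50
            edges = np.concatenate([[0], np.cumsum(widths)]) + start
            exons = [(int(edges[i]), int(edges[i + 1])) for i in range(0, segs, 2)]
            genes.append(GeneModel(gene_id, symbol, chrom, strand,
                                   int(start), end, exons))
    # CpG islands, independent of the genes
    n_islands = max(10, config.n_genes // 2)
    island_alloc = np.maximum(
        np.floor(sizes / sizes.sum() * n_islands).astype(int), 1
    )
    intervals = []
    for chrom, n_i in zip(chroms, island_alloc):
        lengths = rng.integers(300, 1501, size=n_i)
        starts = _place_intervals(rng, config.chrom_sizes[chrom], lengths,
                                  min_gap=100)
        intervals += [(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
    return genes, CpGIslandSet(intervals)


def sample_ids(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    n1, n2 = config.group_sizes
    ids = [f"S{i + 1:02d}" for i in range(n1 + n2)]
    groups = {s: ("group1" if i < n1 else "group2") for i, s in enumerate(ids)}
    return ids, groups


def simulate_methylation(
    config: SimulationConfig,
    genes,
    islands: CpGIslandSet,
    out_dir=None,
):
    """Per-sample CpG count matrices with planted group differences.

    Coverage per site and sample is negative-binomial around
    ``mean_coverage``; the per-sample methylation level is beta around
    the group mean with precision ``beta_binomial_precision``, and the
    methylated count is binomial given both. At DM sites the group-1
    mean is shifted by +/- ``planted_meth_diff`` percentage points.
    Returns (meth counts, unmeth counts, sites table, GroundTruth) and,
    when ``out_dir`` is given, writes one Bismark-dialect coverage file
    per sample under ``out_dir``.
    """
    rng = _streams(config.seed, 5)[1]
    ids, groups = sample_ids(config)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(sizes / sizes.sum() * config.n_cpgs).astype(int)
    alloc[0] += config.n_cpgs - alloc.sum()
    site_chrom, site_pos = [], []
    for chrom, n_c in zip(chroms, alloc):
        pos = np.sort(rng.choice(config.chrom_sizes[chrom], size=n_c,
                                 replace=False))
        site_chrom += [chrom] * n_c
        site_pos += [int(p) for p in pos]
    n_sites = len(site_pos)
    site_id = [f"{c}:{p + 1}" for c, p in zip(site_chrom, site_pos)]

    n_dm = int(round(config.frac_dm_cpgs * n_sites))
    dm_idx = rng.choice(n_sites, size=n_dm, replace=False)
    dm_dir = rng.choice(["hyper", "hypo"], size=n_dm)
    d = config.planted_meth_diff / 100.0
    base = rng.uniform(0.10, 0.90, size=n_sites)
    m1, m2 = base.copy(), base.copy()
    low = rng.uniform(0.02, 0.98 - d, size=n_dm)
    m1[dm_idx] = np.where(dm_dir == "hyper", low + d, low)
    m2[dm_idx] = np.where(dm_dir == "hyper", low, low + d)

    n_samples = len(ids)
    is_g1 = np.array([groups[s] == "group1" for s in ids])
    mean_m = np.where(is_g1[None, :], m1[:, None], m2[:, None])
    if config.coverage_dispersion > 0:
        r = 1.0 / config.coverage_dispersion
        cov = rng.negative_binomial(r, r / (r + config.mean_coverage),
                                    size=(n_sites, n_samples))
    else:
        cov = rng.poisson(config.mean_coverage, size=(n_sites, n_samples))
    prec = config.beta_binomial_precision
    p = rng.beta(np.maximum(mean_m * prec, 1e-6),
                 np.maximum((1 - mean_m) * prec, 1e-6))
    meth = rng.binomial(cov, p)
    unmeth = cov - meth

    sites = pd.DataFrame({"site": site_id, "chrom": site_chrom,
                          "pos": [p + 1 for p in site_pos],
                          "strand": "+"}).set_index("site")
    meth_df = pd.DataFrame(meth, index=sites.index, columns=ids)
    unmeth_df = pd.DataFrame(unmeth, index=sites.index, columns=ids)
    truth = GroundTruth(
        dm_sites={site_id[i] for i in dm_idx},
        dm_direction={site_id[i]: str(dd) for i, dd in zip(dm_idx, dm_dir)},
    )
    truth.validate()
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sid in ids:
            covered = (meth_df[sid] + unmeth_df[sid]) > 0
            df = pd.DataFrame({
                "chrom": sites.loc[covered, "chrom"],
                "start": sites.loc[covered, "pos"],
                "end": sites.loc[covered, "pos"],
                "meth_pct": 100.0 * meth_df.loc[covered, sid]
                / (meth_df.loc[covered, sid] + unmeth_df.loc[covered, sid]),
                "count_meth": meth_df.loc[covered, sid],
                "count_unmeth": unmeth_df.loc[covered, sid],
            })
            io.write_coverage_file(df, os.path.join(out_dir, f"{sid}.cov"))
    return meth_df, unmeth_df, sites, truth


def _truncated_loc(target_mean: float, thr: float, sd: float,
                   lower: bool) -> float:
    """Location of a normal(loc, sd) truncated at ``thr`` (below when
    ``lower`` else above) whose truncated mean equals ``target_mean``."""
    from scipy.optimize import brentq

    def truncated_mean(loc):
        a = (thr - loc) / sd
        if lower:
            return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd)
        return stats.truncnorm.mean(-np.inf, a, loc=loc, scale=sd)

    lo, hi = target_mean - 6 * sd, target_mean + 6 * sd
    return float(brentq(lambda loc: truncated_mean(loc) - target_mean, lo, hi))


def simulate_expression(config: SimulationConfig, genes, out_dir=None):
    """Gene counts, clinical covariate table and planted DE truth.

    Counts are negative-binomial with per-gene log-normal base means
    (median ~100), log-normal(0, 0.2) size factors and dispersion
    ``nb_dispersion``; DE genes have the group-1 mean scaled by
    2^(+/- planted_log2fc). The covariate table carries the HbA1c-like
    value (drawn from group normals truncated at the midpoint threshold,
    so group membership equals the threshold rule exactly) plus
    Table-1-style null covariates.
    """
    rng = _streams(config.seed, 5)[2]
    ids, groups = sample_ids(config)
    n1, n2 = config.group_sizes
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)

    m1 = config.covariate_mean_by_group["group1"]
    m2 = config.covariate_mean_by_group["group2"]
    if m1 <= m2:
        raise ConfigError("group1 covariate mean must exceed group2's")
    thr = 0.5 * (m1 + m2)
    sd = config.covariate_sd
    # choose the truncated-normal locations so the *realised* group means
    # hit the configured ones despite the threshold truncation
    loc1 = _truncated_loc(m1, thr, sd, lower=True)
    loc2 = _truncated_loc(m2, thr, sd, lower=False)
    hba1c_g1 = stats.truncnorm.rvs((thr - loc1) / sd, np.inf, loc=loc1,
                                   scale=sd, size=n1, random_state=rng)
    hba1c_g2 = stats.truncnorm.rvs(-np.inf, (thr - loc2) / sd, loc=loc2,
                                   scale=sd, size=n2, random_state=rng)
    covariates = pd.DataFrame({
        "sample": ids,
        "group": [groups[s] for s in ids],
        "hba1c": np.round(np.concatenate([hba1c_g1, hba1c_g2]), 2),
        "age": np.round(rng.normal(56.4, 8.0, size=n1 + n2), 1),
        "sex": rng.choice(["male", "female"], size=n1 + n2, p=[0.62, 0.38]),
        "bmi": np.round(rng.normal(30.6, 5.8, size=n1 + n2), 1),
        "cholesterol": np.round(rng.normal(5.8, 1.2, size=n1 + n2), 2),
        "triglyceride": np.round(np.clip(rng.normal(2.8, 2.1, size=n1 + n2),
                                         0.3, None), 2),
        "diabetes_duration": np.round(np.clip(rng.normal(9.3, 6.5, size=n1 + n2),
                                              1.0, None), 1),
        "treatment": rng.choice(["treated", "placebo"], size=n1 + n2,
                                p=[0.66, 0.34]),
    }).set_index("sample")

    n_de = int(round(config.frac_de_genes * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_dir = rng.choice(["up", "down"], size=n_de)
    log2fc = np.zeros(n_genes)
    log2fc[de_idx] = np.where(de_dir == "up", config.planted_log2fc,
                              -config.planted_log2fc)
    base = rng.lognormal(np.log(100.0), 1.0, size=n_genes)
    sf = rng.lognormal(0.0, 0.2, size=n1 + n2)
    is_g1 = np.array([groups[s] == "group1" for s in ids])
    mu = base[:, None] * np.where(is_g1[None, :],
                                  2.0 ** log2fc[:, None], 1.0) * sf[None, :]
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=ids)
    truth = GroundTruth(
        de_genes={gene_ids[i] for i in de_idx},
        de_direction={gene_ids[i]: str(dd) for i, dd in zip(de_idx, de_dir)},
    )
    truth.validate()
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        counts_df.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
        covariates.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t")
    return counts_df, covariates, truth


def simulate_gene_sets(genes, config: SimulationConfig,
                       expression_truth: GroundTruth | None = None,
                       n_terms: int = 40):
    """A toy GMT collection over the valid gene symbols.

    Includes two families of near-duplicate terms (shared gene cores) so
    kappa-based term clustering has structure to find, plus independent
    random terms. When the planted DE truth is supplied the family cores
    are seeded preferentially from DE genes, giving the DEG enrichment
    run real over-representation to detect.
    """
    rng = _streams(config.seed, 5)[3]
    symbols = sorted(g.symbol for g in genes if g.symbol)
    by_id = {g.gene_id: g.symbol for g in genes if g.symbol}
    de_symbols = sorted(
        by_id[g] for g in (expression_truth.de_genes if expression_truth else [])
        if g in by_id
    )
    collection: dict[str, dict] = {}
    term_no = 0
    for family in range(2):
        core_size = min(30, max(len(symbols) // 2, 1))
        # seed only about half the DE genes per family: terms covering the
        # whole query make kappa degenerate (chance agreement = observed)
        n_de_core = min(len(de_symbols) // 2, 20, core_size)
        core = list(rng.choice(de_symbols, size=n_de_core, replace=False)) \
            if n_de_core else []
        core += list(rng.choice(symbols, size=core_size - len(core),
                                replace=False))
        for _ in range(6):
            term_no += 1
            keep = [g for g in core if rng.random() < 0.9]
            extra = list(rng.choice(symbols, size=3, replace=False))
            collection[f"TERM{term_no:04d}"] = {
                "name": f"toy process family {family + 1}",
                "genes": set(keep) | set(extra),
            }
    max_size = min(60, len(symbols))
    while term_no < n_terms:
        term_no += 1
        size = int(rng.integers(min(10, max_size), max_size + 1))
        collection[f"TERM{term_no:04d}"] = {
            "name": f"toy process {term_no}",
            "genes": set(rng.choice(symbols, size=size, replace=False)),
        }
    return collection


def simulate_interactions(genes, config: SimulationConfig,
                          expression_truth: GroundTruth | None = None,
                          n_background: int = 400) -> pd.DataFrame:
    """A toy interaction edge table with confidence scores in [0, 1].

    High-confidence (> 0.9) communities are planted preferentially among
    the planted DE genes so the score-filtered DEG network is non-empty.
    """
    rng = _streams(config.seed, 5)[4]
    by_id = {g.gene_id: g.symbol for g in genes if g.symbol}
    symbols = sorted(by_id.values())
    preferred = sorted(
        by_id[g] for g in (expression_truth.de_genes if expression_truth else [])
        if g in by_id
    )
    edges = []
    # two planted high-confidence communities
    pool = preferred if len(preferred) >= 12 else symbols
    hubs = list(rng.choice(pool, size=min(16, len(pool)), replace=False))
    half = len(hubs) // 2
    for community in (hubs[:half], hubs[half:]):
        for i, a in enumerate(community):
            for b in community[i + 1:]:
                if rng.random() < 0.6:
                    edges.append((a, b, float(rng.uniform(0.905, 1.0))))
    for _ in range(n_background):
        a, b = rng.choice(symbols, size=2, replace=False)
        edges.append((a, b, float(np.round(rng.beta(2, 2), 3))))
    return pd.DataFrame(edges, columns=["gene_a", "gene_b", "score"])


def write_ground_truth(meth_truth: GroundTruth, expr_truth: GroundTruth,
                       path) -> None:
    rows = [("dm_site", s, meth_truth.dm_direction[s])
            for s in sorted(meth_truth.dm_sites)]
    rows += [("de_gene", g, expr_truth.de_direction[g])
             for g in sorted(expr_truth.de_genes)]
    pd.DataFrame(rows, columns=["kind", "id", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def simulate_study(config: SimulationConfig, out_dir) -> dict:
    """Generate the complete synthetic study on disk.

    Writes genes.gtf, islands.bed, per-sample coverage files, counts.tsv,
    samples.tsv, gene_sets.gmt, edges.tsv and truth.tsv under ``out_dir``
    and returns a path manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    genes, islands = generate_annotation(config)
    gtf = os.path.join(out_dir, "genes.gtf")
    bed = os.path.join(out_dir, "islands.bed")
    io.write_gtf(genes, gtf)
    io.write_islands_bed(islands, bed)
    cov_dir = os.path.join(out_dir, "coverage")
    _, _, _, meth_truth = simulate_methylation(config, genes, islands, cov_dir)
    counts, covariates, expr_truth = simulate_expression(config, genes, out_dir)
    gene_sets = simulate_gene_sets(genes, config, expr_truth)
    gmt = os.path.join(out_dir, "gene_sets.gmt")
    io.write_gmt(gene_sets, gmt)
    edges = simulate_interactions(genes, config, expr_truth)
    edges_path = os.path.join(out_dir, "edges.tsv")
    edges.to_csv(edges_path, sep="\t", index=False)
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_ground_truth(meth_truth, expr_truth, truth_path)
    ids, _ = sample_ids(config)
    return {
        "gtf": gtf, "islands": bed, "coverage_dir": cov_dir,
        "coverage_files": [os.path.join(cov_dir, f"{s}.cov") for s in ids],
        "samples": ids,
        "counts": os.path.join(out_dir, "counts.tsv"),
        "covariates": os.path.join(out_dir, "samples.tsv"),
        "gmt": gmt, "edges": edges_path, "truth": truth_path,
    }
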