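"""Differential CpG methylation from bisulfite coverage files.

The per-site methylation level is #C / (#C + #T), reported as a
percentage. Sites are retained when their read coverage strictly exceeds
``min_coverage`` in at least ``min_per_group`` samples of each group and
they do not lie on an excluded (sex) chromosome. Differential
methylation is tested per site with a binomial logistic regression of
(#C, #T) on the group indicator; with a single binary covariate the
maximum-likelihood group proportions are the pooled proportions, so the
likelihood-ratio statistic is computed in closed form from pooled
counts. A pooled 2x2 Fisher's exact test is available as a cross-check.

DMCs are sites with |methylation difference| strictly above the
difference threshold (default 15 percentage points) and a
Benjamini-Hochberg q-value strictly below the q threshold (default
0.01); hypermethylated means group 1 above group 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .io import read_coverage_file


class MethylationError(ValueError):
    pass


@dataclass
class MethylationFilterConfig:
    """CpG retention filters.

    ``min_coverage`` is exclusive (a site needs coverage > 10 by default)
    and ``min_quality`` documents the read-level Phred filter applied
    upstream of coverage files; it cannot be re-applied to count data and
    is recorded here only for provenance.
    """

    min_coverage: int = 10
    min_quality: int = 20
    min_per_group: int = 10
    excluded_chromosomes: frozenset = field(
        default_factory=lambda: frozenset({"chrX", "chrY"})
    )


@dataclass
class CpGCountMatrix:
    """Per-site x per-sample methylated/unmethylated read counts.

    ``meth`` and ``unmeth`` share a site-id index ("chrom:pos", position
    1-based as in the coverage dialect) and sample columns; ``sites``
    maps site id to (chrom, pos, strand).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index):
            raise MethylationError("meth/unmeth site indices differ")
        if list(self.meth.columns) != list(self.unmeth.columns):
            raise MethylationError("meth/unmeth sample columns differ")
        if (self.meth.values < 0).any() or (self.unmeth.values < 0).any():
            raise MethylationError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def coverage(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def __len__(self) -> int:
        return len(self.meth)


def read_coverage_files(
    paths: Sequence, sample_ids: Sequence[str]
) -> CpGCountMatrix:
    """Load one coverage file per sample into the union-of-sites matrix.

    A site missing from a sample's file gets coverage 0 there. The
    percentage column of the files is ignored; levels are recomputed
    from counts.
    """
    if len(paths) != len(sample_ids):
        raise MethylationError("one coverage path per sample id required")
    meth_cols, unmeth_cols = {}, {}
    site_info: dict[str, tuple[str, int]] = {}
    for path, sid in zip(paths, sample_ids):
        df = read_coverage_file(path)
        ids = df["chrom"].astype(str) + ":" + df["start"].astype(str)
        meth_cols[sid] = pd.Series(df["count_meth"].values, index=ids)
        unmeth_cols[sid] = pd.Series(df["count_unmeth"].values, index=ids)
        for site, chrom, pos in zip(ids, df["chrom"], df["start"]):
            site_info.setdefault(site, (chrom, int(pos)))
    order = sorted(site_info, key=lambda s: (site_info[s][0], site_info[s][1]))
    meth = pd.DataFrame(meth_cols, index=order).fillna(0).astype(int)
    unmeth = pd.DataFrame(unmeth_cols, index=order).fillna(0).astype(int)
    sites = pd.DataFrame(
        [(s, *site_info[s], "+") for s in order],
        columns=["site", "chrom", "pos", "strand"],
    ).set_index("site")
    return CpGCountMatrix(meth, unmeth, sites)


def methylation_percent(count_meth, count_unmeth):
    """Methylation level 100 * #C / (#C + #T); NaN where coverage is 0."""
    count_meth = np.asarray(count_meth, dtype=float)
    count_unmeth = np.asarray(count_unmeth, dtype=float)
    if (count_meth < 0).any() or (count_unmeth < 0).any():
        raise MethylationError("counts must be non-negative")
    cov = count_meth + count_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * count_meth / cov, np.nan)
    if pct.ndim == 0:
        return float(pct)
    return pct


def _group_columns(
    samples: Sequence[str], groups: Mapping[str, str]
) -> tuple[str, str, list[str], list[str]]:
    missing = [s for s in samples if s not in groups]
    if missing:
        raise MethylationError(f"samples without group assignment: {missing}")
    labels = sorted(set(groups[s] for s in samples))
    if len(labels) != 2:
        raise MethylationError(f"exactly two groups required, got {labels}")
    g1, g2 = labels
    return (g1, g2,
            [s for s in samples if groups[s] == g1],
            [s for s in samples if groups[s] == g2])


def filter_sites(
    matrix: CpGCountMatrix,
    groups: Mapping[str, str],
    config: MethylationFilterConfig | None = None,
) -> CpGCountMatrix:
    """Apply the retention filters; see the module docstring for the rule."""
    config = config or MethylationFilterConfig()
    g1, g2, cols1, cols2 = _group_columns(matrix.samples, groups)
    if min(len(cols1), len(cols2)) < config.min_per_group:
        raise MethylationError(
            f"min_per_group={config.min_per_group} exceeds the smallest "
            f"group size ({min(len(cols1), len(cols2))})"
        )
    cov = matrix.coverage
    covered = cov > config.min_coverage  # strict: coverage 10 is dropped
    keep = (
        (covered[cols1].sum(axis=1) >= config.min_per_group)
        & (covered[cols2].sum(axis=1) >= config.min_per_group)
        & ~matrix.sites["chrom"].isin(config.excluded_chromosomes)
    )
    return CpGCountMatrix(
        matrix.meth.loc[keep], matrix.unmeth.loc[keep], matrix.sites.loc[keep]
    )


def _binomial_lrt(c1, t1, c2, t2):
    """Closed-form likelihood-ratio test of group effect in a binomial
    logistic regression, vectorised over sites.

    With only an intercept and a binary group covariate the fitted
    per-group probabilities are the pooled proportions, so the deviance
    difference depends on pooled counts alone; p from chi-square, 1 df.
    """
    c1, t1, c2, t2 = (np.asarray(a, dtype=float) for a in (c1, t1, c2, t2))
    n1, n2 = c1 + t1, c2 + t2
    c, t = c1 + c2, t1 + t2
    n = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        ll_full = (xlogy(c1, c1 / n1) + xlogy(t1, t1 / n1)
                   + xlogy(c2, c2 / n2) + xlogy(t2, t2 / n2))
        ll_null = xlogy(c, c / n) + xlogy(t, t / n)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    return stats.chi2.sf(stat, df=1)


def test_dm(
    matrix: CpGCountMatrix,
    groups: Mapping[str, str],
    method: str = "lrt",
) -> pd.DataFrame:
    """Per-site group methylation means, difference and p-value.

    The methylation difference is the difference of per-sample mean
    percentages (group 1 minus group 2); samples with zero coverage at a
    site are excluded from that site's means. ``method`` selects the
    binomial-logistic likelihood-ratio test ("lrt", default) or a pooled
    2x2 Fisher's exact cross-check ("fisher").
    """
    if method not in ("lrt", "fisher"):
        raise MethylationError(f"unknown test method {method!r}")
    g1, g2, cols1, cols2 = _group_columns(matrix.samples, groups)
    meth, unmeth = matrix.meth, matrix.unmeth
    pct = pd.DataFrame(
        methylation_percent(meth.values, unmeth.values),
        index=meth.index, columns=meth.columns,
    )
    mean1 = pct[cols1].mean(axis=1, skipna=True)
    mean2 = pct[cols2].mean(axis=1, skipna=True)
    one_sided = mean1.isna() | mean2.isna()
    if one_sided.any():
        warnings.warn(
            f"{int(one_sided.sum())} sites covered in only one group were excluded"
        )
    c1 = meth[cols1].sum(axis=1).values
    t1 = unmeth[cols1].sum(axis=1).values
    c2 = meth[cols2].sum(axis=1).values
    t2 = unmeth[cols2].sum(axis=1).values
    if method == "lrt":
        p = _binomial_lrt(c1, t1, c2, t2)
    else:
        p = np.array(
            [stats.fisher_exact([[a, b], [c, d]])[1]
             for a, b, c, d in zip(c1, t1, c2, t2)]
        )
    out = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "pos": matrix.sites["pos"],
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "meth_diff": mean1 - mean2,
            "p_value": p,
        },
        index=meth.index,
    )
    out.index.name = "site"
    return out.loc[~one_sided]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_dmcs(
    results: pd.DataFrame,
    diff_threshold: float = 15.0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Call DMCs at |meth_diff| > diff_threshold and q < q_threshold
    (both strict) and attach the hyper/hypo direction."""
    res = results.copy()
    if "q_value" not in res.columns:
        res["q_value"] = adjust_bh(res["p_value"].values)
    keep = (res["meth_diff"].abs() > diff_threshold) & (res["q_value"] < q_threshold)
    dmc = res.loc[keep].copy()
    dmc["direction"] = np.where(dmc["meth_diff"] > 0, "hyper", "hypo")
    return dmc.sort_values("q_value")
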