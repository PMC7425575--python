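"""Expression normalisation, data-driven sample grouping and
differential expression.

Counts are normalised with median-of-ratios size factors. Samples are
grouped by unsupervised hierarchical clustering of log2(normalised
count + 1) profiles (1 - Pearson correlation distance, average linkage)
cut at k clusters; the two analysis groups are the clusters with the
highest and lowest mean HbA1c-like covariate ("group1" = highest).
Differential expression uses a simplified per-gene negative-binomial
Wald test with method-of-moments dispersion, with size factors as
exposure; genes with BH-adjusted p strictly below 0.01 are DEGs.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.api as sm

from .methylome import adjust_bh


class ExpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over genes with a positive geometric mean of
    count_gs / geomean_g. Requires at least one gene expressed in every
    sample.
    """
    if counts.shape[1] < 2:
        raise ExpressionError("size factors need at least two samples")
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(x).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ExpressionError("no gene has nonzero counts in every sample")
    ratios = x[usable] / np.exp(loggeo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    factors = size_factors(counts) if factors is None else factors
    return counts / factors


def exon_union_length(exons: Sequence[tuple[int, int]]) -> int:
    """Total bp covered by the union of (possibly overlapping) exons."""
    total, last_end = 0, None
    for s, e in sorted(exons):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def fpkm(counts: pd.DataFrame, gene_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped reads.

    FPKM_gs = count_gs / (length_g/1000 * total_s/1e6); gene length is
    the exon-union length.
    """
    missing = [g for g in counts.index if g not in gene_lengths]
    if missing:
        raise ExpressionError(f"genes without length: {missing[:10]}"
                              + ("..." if len(missing) > 10 else ""))
    lengths = np.array([gene_lengths[g] for g in counts.index], dtype=float)
    if (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    vals = counts.to_numpy(dtype=float) / (
        (lengths[:, None] / 1e3) * (totals[None, :] / 1e6)
    )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# sample clustering and covariate association
# ---------------------------------------------------------------------------

def cluster_samples(counts: pd.DataFrame, k: int = 3,
                    factors: pd.Series | None = None) -> pd.Series:
    """Hierarchical clustering of samples on log2(normalised count + 1).

    Distance 1 - Pearson correlation, average linkage, cut at k
    clusters. Labels ("cluster1"...) are deterministic for fixed input.
    """
    n = counts.shape[1]
    if k > n:
        raise ExpressionError(f"k={k} exceeds the number of samples ({n})")
    if k < 1:
        raise ExpressionError("k must be >= 1")
    logx = np.log2(normalized_counts(counts, factors) + 1.0)
    corr = np.corrcoef(logx.to_numpy().T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series([f"cluster{i}" for i in labels], index=counts.columns,
                     name="cluster")


def select_extreme_clusters(
    labels: pd.Series, covariate: pd.Series
) -> dict[str, str]:
    """Name the clusters with the highest and lowest mean covariate
    "group1" and "group2"; return sample -> group for those samples."""
    means = covariate.groupby(labels).mean().sort_values(ascending=False)
    hi, lo = means.index[0], means.index[-1]
    if hi == lo:
        raise ExpressionError("need at least two clusters to pick extremes")
    out = {}
    for sample, lab in labels.items():
        if lab == hi:
            out[sample] = "group1"
        elif lab == lo:
            out[sample] = "group2"
    return out


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sided Student's t from group summaries.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def associate_covariates(
    groups: Mapping[str, str],
    sample_table: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Associate clinical covariates with the two selected groups.

    Continuous covariates get a two-sided two-sample Student's t test
    (pooled variance by default, Welch optional); categorical ones get
    Fisher's exact test on the 2x2 table. A joint logistic regression of
    group membership on all covariates reports per-covariate Wald p.
    Constant covariates are reported with p = 1 and a warning.
    """
    table = sample_table.loc[list(groups)]
    y = np.array([1 if groups[s] == "group1" else 0 for s in table.index])
    if covariates is None:
        covariates = [c for c in table.columns
                      if c not in ("sample", "group", "cluster")]
    rows = []
    X = pd.DataFrame(index=table.index)
    for cov in covariates:
        col = table[cov]
        numeric = pd.api.types.is_numeric_dtype(col) and col.nunique() > 2
        if col.nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {cov!r} is constant; p set to 1")
            rows.append((cov, "constant", 1.0))
            continue
        if numeric:
            a = col[y == 1].astype(float)
            b = col[y == 0].astype(float)
            if welch:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            else:
                _, _, p = ttest_from_summary(
                    a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
                )
            test = "t-test"
            X[cov] = col.astype(float)
        else:
            codes, _ = pd.factorize(col)
            tab = pd.crosstab(codes, y)
            if tab.shape == (2, 2):
                p = stats.fisher_exact(tab.values)[1]
            else:
                p = stats.chi2_contingency(tab.values)[1]
            test = "fisher"
            X[cov] = codes.astype(float)
        rows.append((cov, test, float(p)))
    out = pd.DataFrame(rows, columns=["covariate", "test", "p_value"])
    # joint multifactorial logistic regression with per-covariate Wald p
    logit_p = pd.Series(np.nan, index=out["covariate"])
    varying = [c for c in X.columns if X[c].nunique() > 1]
    if varying:
        Xd = sm.add_constant((X[varying] - X[varying].mean()) / X[varying].std())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            for c in varying:
                logit_p[c] = fit.pvalues[c]
        except Exception as exc:  # perfect separation and friends
            warnings.warn(f"joint logistic regression failed: {exc}")
    out["logit_wald_p"] = logit_p.values
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def drop_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every sample."""
    return counts.loc[counts.sum(axis=1) > 0]


def test_de(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    factors: pd.Series | None = None,
    adj_p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Simplified per-gene negative-binomial Wald test of the group effect.

    Per gene: normalise by size factors, estimate the two group means,
    estimate the dispersion by method of moments on within-group
    residual variance (floored at 1e-8), and test the log fold change
    with a Wald statistic whose variance comes from the NB mean-variance
    relation var = mu + alpha mu^2. BH adjustment across genes; DEG call
    at adjusted p strictly below ``adj_p_threshold``, direction by the
    sign of the log2 fold change (group1 over group2).
    """
    samples = list(counts.columns)
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ExpressionError(f"samples without group assignment: {missing}")
    labels = sorted(set(groups[s] for s in samples))
    if len(labels) != 2:
        raise ExpressionError(f"exactly two groups required, got {labels}")
    g1, g2 = ("group1", "group2") if set(labels) == {"group1", "group2"} else labels
    cols1 = [s for s in samples if groups[s] == g1]
    cols2 = [s for s in samples if groups[s] == g2]
    if min(len(cols1), len(cols2)) < 2:
        raise ExpressionError("each group needs at least two samples")
    counts = drop_zero_genes(counts)
    factors = size_factors(counts) if factors is None else factors

    y = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    idx1 = [counts.columns.get_loc(s) for s in cols1]
    idx2 = [counts.columns.get_loc(s) for s in cols2]
    y1, y2 = y[:, idx1], y[:, idx2]
    n1, n2 = y1.shape[1], y2.shape[1]
    q1, q2 = y1.mean(axis=1), y2.mean(axis=1)

    # method-of-moments dispersion from within-group residual variance
    resid = np.concatenate([y1 - q1[:, None], y2 - q2[:, None]], axis=1)
    s2 = (resid**2).sum(axis=1) / (n1 + n2 - 2)
    qbar = (n1 * q1 + n2 * q2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(qbar > 0, (s2 - qbar) / qbar**2, 0.0)
    alpha = np.clip(alpha, 1e-8, None)

    pseudo = 0.5
    log2fc = np.log2(q1 + pseudo) - np.log2(q2 + pseudo)
    inv_sf = 1.0 / factors.reindex(counts.columns).to_numpy()
    s1 = inv_sf[idx1].sum() / n1**2
    s2f = inv_sf[idx2].sum() / n2**2
    q1s, q2s = np.maximum(q1, pseudo), np.maximum(q2, pseudo)
    var_log = (s1 / q1s + alpha / n1) + (s2f / q2s + alpha / n2)
    wald = (np.log(q1 + pseudo) - np.log(q2 + pseudo)) / np.sqrt(var_log)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    adj = adjust_bh(p)
    out = pd.DataFrame(
        {
            "base_mean": qbar,
            "log2_fold_change": log2fc,
            "dispersion": alpha,
            "p_value": p,
            "adjusted_p": adj,
            "is_deg": adj < adj_p_threshold,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=counts.index,
    )
    out.index.name = "gene_id"
    return out


def call_degs(results: pd.DataFrame) -> pd.DataFrame:
    return results.loc[results["is_deg"]].sort_values("adjusted_p")
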