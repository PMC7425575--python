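"""Normalisation, clustering, covariate association and NB differential
expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import methylink as ml
from methylink.transcriptome import (ExpressionError, call_degs,
                                     drop_zero_genes, exon_union_length,
                                     normalized_counts, select_extreme_clusters)


def _counts(values, samples=None):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(len(df))]
    df.columns = samples or [f"S{i + 1}" for i in range(df.shape[1])]
    return df


# ---------------------------------------------------------------- size factors

def test_identical_samples_have_unit_factors():
    c = _counts({0: [10, 20, 30], 1: [10, 20, 30], 2: [10, 20, 30]})
    assert np.allclose(ml.size_factors(c), 1.0)


def test_doubled_sample_has_doubled_factor(rng):
    base = rng.integers(1, 500, size=50)
    c = _counts({0: base, 1: base * 2, 2: base})
    f = ml.size_factors(c)
    assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)


def test_factors_invariant_to_gene_order(rng):
    c = _counts({0: rng.integers(1, 100, 30), 1: rng.integers(1, 100, 30)})
    shuffled = c.sample(frac=1.0, random_state=1)
    assert np.allclose(ml.size_factors(c), ml.size_factors(shuffled))


def test_no_universally_expressed_gene_errors():
    c = _counts({0: [5, 0], 1: [0, 5]})
    with pytest.raises(ExpressionError):
        ml.size_factors(c)


# ---------------------------------------------------------------- FPKM

def test_fpkm_worked_example():
    c = _counts({0: [100], 1: [100]})
    c.iloc[:, :] = 100
    # one gene, length 1000 bp; library = 100 reads -> scale to 1e6 manually
    counts = pd.DataFrame({"S1": [100, 1e6 - 100]}, index=["g", "filler"])
    out = ml.fpkm(counts, {"g": 1000, "filler": 1000})
    assert out.loc["g", "S1"] == pytest.approx(100.0)


def test_doubling_library_halves_fpkm():
    counts = pd.DataFrame({"S1": [100, 900], "S2": [200, 1800]},
                          index=["g", "h"])
    out = ml.fpkm(counts, {"g": 1000, "h": 1000})
    assert out.loc["g", "S2"] == pytest.approx(out.loc["g", "S1"])
    doubled = ml.fpkm(counts.assign(S1=counts["S1"] * 2)[["S1"]],
                      {"g": 1000, "h": 1000})
    # same gene count with a doubled library -> half the FPKM
    single = ml.fpkm(counts[["S1"]], {"g": 1000, "h": 1000})
    assert ml.fpkm(
        pd.DataFrame({"S1": [100, 1900]}, index=["g", "h"]), {"g": 1000, "h": 1000}
    ).loc["g", "S1"] == pytest.approx(single.loc["g", "S1"] / 2)


def test_exon_union_handles_overlap():
    assert exon_union_length([(100, 200), (150, 300)]) == 200
    assert exon_union_length([(0, 50), (100, 150)]) == 100


def test_missing_length_errors():
    counts = pd.DataFrame({"S1": [1]}, index=["g"])
    with pytest.raises(ExpressionError, match="g"):
        ml.fpkm(counts, {})


# ---------------------------------------------------------------- clustering

def test_k1_gives_single_cluster(rng):
    c = _counts(rng.integers(0, 100, size=(40, 6)))
    labels = ml.cluster_samples(c, k=1)
    assert labels.nunique() == 1


def test_k_exceeding_samples_errors(rng):
    c = _counts(rng.integers(0, 100, size=(10, 3)))
    with pytest.raises(ExpressionError):
        ml.cluster_samples(c, k=4)


def test_duplicated_columns_cluster_together(rng):
    vals = rng.integers(0, 300, size=(60, 4))
    c = _counts(np.column_stack([vals, vals[:, 0]]),
                samples=["A", "B", "C", "D", "Adup"])
    labels = ml.cluster_samples(c, k=3)
    assert labels["A"] == labels["Adup"]


def test_planted_groups_recovered_exactly(small_expression):
    counts, covariates, _ = small_expression
    labels = ml.cluster_samples(drop_zero_genes(counts), k=2)
    truth = covariates["group"]
    assert adjusted_rand_score(truth, labels[truth.index]) == pytest.approx(1.0)
    groups = select_extreme_clusters(labels, covariates["hba1c"])
    assert all(groups[s] == truth[s] for s in truth.index)


# ---------------------------------------------------------------- t test

def test_hba1c_group_summary_t_test_rounds_to_004():
    t, df, p = ml.ttest_from_summary(8.7, 1.6, 21, 7.8, 1.4, 32)
    assert df == 51
    assert round(p, 2) == 0.04


def test_equal_means_give_t_zero_p_one():
    t, _, p = ml.ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_from_summary_matches_numeric_cdf():
    t, df, p = ml.ttest_from_summary(0, 1, 10, 1, 1, 10)
    assert t == pytest.approx(-2.2360679, abs=1e-4)
    assert df == 18
    assert p == pytest.approx(2 * stats.t.cdf(-2.2360679, 18), abs=1e-4)
    assert p == pytest.approx(0.0382, abs=1e-4)


def test_summary_t_matches_scipy_on_raw_data(rng):
    a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1.2, 20)
    t, _, p = ml.ttest_from_summary(a.mean(), a.std(ddof=1), len(a),
                                    b.mean(), b.std(ddof=1), len(b))
    ref = stats.ttest_ind(a, b, equal_var=True)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


@pytest.mark.parametrize("bad", [dict(n1=1), dict(sd1=0.0), dict(sd2=-1.0)])
def test_invalid_summary_inputs_error(bad):
    kwargs = dict(mean1=1, sd1=1, n1=10, mean2=0, sd2=1, n2=10)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        ml.ttest_from_summary(**kwargs)


# ---------------------------------------------------------------- covariates

def test_constant_covariate_reports_p_one():
    table = pd.DataFrame({"flat": [1.0] * 8}, index=[f"S{i}" for i in range(8)])
    groups = {f"S{i}": ("group1" if i < 4 else "group2") for i in range(8)}
    with pytest.warns(UserWarning, match="constant"):
        out = ml.associate_covariates(groups, table)
    assert out.loc[out["covariate"] == "flat", "p_value"].iloc[0] == 1.0


def test_perfectly_split_categorical_matches_hypergeometric():
    # 2x2 table [[10, 0], [0, 10]]: two-sided Fisher p = 2 / C(20, 10)
    table = pd.DataFrame(
        {"sex": ["male"] * 10 + ["female"] * 10},
        index=[f"S{i}" for i in range(20)],
    )
    groups = {f"S{i}": ("group1" if i < 10 else "group2") for i in range(20)}
    out = ml.associate_covariates(groups, table)
    from math import comb
    expected = 2 / comb(20, 10)
    assert out["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)
    assert out["p_value"].iloc[0] == pytest.approx(1.08e-5, rel=0.01)


def test_mirrored_continuous_covariate_p_one():
    vals = [1.0, 2.0, 3.0, 4.0]
    table = pd.DataFrame({"x": vals + vals}, index=[f"S{i}" for i in range(8)])
    groups = {f"S{i}": ("group1" if i < 4 else "group2") for i in range(8)}
    out = ml.associate_covariates(groups, table)
    assert out["p_value"].iloc[0] == pytest.approx(1.0)


def test_simulated_covariates_flag_hba1c(small_expression):
    counts, covariates, _ = small_expression
    groups = dict(covariates["group"])
    out = ml.associate_covariates(
        groups, covariates.drop(columns=["group"])
    ).set_index("covariate")
    assert out.loc["hba1c", "p_value"] < 0.01
    null_covs = ["age", "bmi", "cholesterol", "triglyceride"]
    assert (out.loc[null_covs, "p_value"] > 0.01).sum() >= 3


# ---------------------------------------------------------------- DE test

def test_all_zero_gene_never_reaches_testing(small_expression):
    counts, covariates, _ = small_expression
    counts = counts.copy()
    counts.loc["gZERO"] = 0
    res = ml.test_de(counts, dict(covariates["group"]))
    assert "gZERO" not in res.index


def test_label_swap_negates_log2fc(small_expression):
    counts, covariates, _ = small_expression
    groups = dict(covariates["group"])
    swapped = {s: ("group2" if g == "group1" else "group1")
               for s, g in groups.items()}
    r1 = ml.test_de(counts, groups)
    r2 = ml.test_de(counts, swapped)
    assert np.allclose(r1["log2_fold_change"], -r2["log2_fold_change"])
    d1, d2 = call_degs(r1), call_degs(r2)
    assert (d1["direction"] == "up").sum() == (d2["direction"] == "down").sum()


def test_up_down_partition(small_expression):
    counts, covariates, _ = small_expression
    degs = call_degs(ml.test_de(counts, dict(covariates["group"])))
    assert ((degs["direction"] == "up").sum()
            + (degs["direction"] == "down").sum()) == len(degs)


def test_nb_wald_agrees_with_deseq2_oracle():
    """Independent cross-check of the simplified NB Wald test against a
    full shrunken-dispersion fit on a small simulated matrix."""
    import warnings
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = ml.SimulationConfig(n_samples_per_group=10, n_genes=150, n_cpgs=10,
                              frac_de_genes=0.2, seed=2)
    genes, _ = ml.generate_annotation(cfg)
    counts, cov, _ = ml.simulate_expression(cfg, genes)
    ours = ml.test_de(counts, dict(cov["group"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=counts.T,
                           metadata=pd.DataFrame({"condition": cov["group"]}),
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "group1", "group2"],
                        quiet=True)
        ds.summary()
    ref = ds.results_df
    common = ours.index.intersection(ref.index)
    r = np.corrcoef(ours.loc[common, "log2_fold_change"],
                    ref.loc[common, "log2FoldChange"])[0, 1]
    assert r > 0.99
    strong = common[ref.loc[common, "padj"].fillna(1) < 1e-4]
    assert (np.sign(ours.loc[strong, "log2_fold_change"])
            == np.sign(ref.loc[strong, "log2FoldChange"])).all()
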