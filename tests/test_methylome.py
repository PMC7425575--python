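"""Coverage-file ingestion, retention filters, per-CpG testing and DMC calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylink as ml
from methylink.io import ParseError
from methylink.methylome import MethylationError, _binomial_lrt
from methylink.simulate import sample_ids

from conftest import make_matrix


# ---------------------------------------------------------------- parsing

def _write(tmp_path, name, rows):
    path = tmp_path / name
    path.write_text("".join(f"{r}\n" for r in rows))
    return path


def test_single_row_coverage_file(tmp_path):
    p = _write(tmp_path, "a.cov", ["chr1\t100\t100\t50.0\t5\t5"])
    m = ml.read_coverage_files([p], ["A"])
    assert len(m) == 1
    assert m.meth.loc["chr1:100", "A"] == 5
    assert m.unmeth.loc["chr1:100", "A"] == 5


def test_union_of_disjoint_sites_fills_zero_coverage(tmp_path):
    pa = _write(tmp_path, "a.cov", ["chr1\t100\t100\t50.0\t5\t5"])
    pb = _write(tmp_path, "b.cov", ["chr1\t200\t200\t0.0\t0\t8"])
    m = ml.read_coverage_files([pa, pb], ["A", "B"])
    assert len(m) == 2
    assert m.coverage.loc["chr1:200", "A"] == 0
    assert m.coverage.loc["chr1:100", "B"] == 0


@pytest.mark.parametrize("row", [
    "chr1\t100\t100\t50.0\t-1\t5",       # negative count
    "chr1\t100\t100\t50.0\t5.5\t5",      # non-integer count
])
def test_malformed_rows_raise_parse_error(tmp_path, row):
    p = _write(tmp_path, "bad.cov", ["chr1\t50\t50\t0\t0\t3", row])
    with pytest.raises(ParseError, match="line 2"):
        ml.read_coverage_files([p], ["A"])


def test_duplicate_site_within_file_raises(tmp_path):
    p = _write(tmp_path, "dup.cov",
               ["chr1\t100\t100\t50.0\t5\t5", "chr1\t100\t100\t50.0\t1\t1"])
    with pytest.raises(ParseError, match="duplicate"):
        ml.read_coverage_files([p], ["A"])


# ---------------------------------------------------------------- levels

@pytest.mark.parametrize("c,t,expected", [(5, 5, 50.0), (0, 10, 0.0), (7, 3, 70.0)])
def test_methylation_percent_worked_examples(c, t, expected):
    assert ml.methylation_percent(c, t) == pytest.approx(expected)


def test_zero_coverage_is_missing():
    assert np.isnan(ml.methylation_percent(0, 0))


# ---------------------------------------------------------------- filters

def _uniform_matrix(cov, n_samples=24, chrom="chr1"):
    c = cov // 2
    meth = {f"{chrom}:100": [c] * n_samples}
    unmeth = {f"{chrom}:100": [cov - c] * n_samples}
    return make_matrix(meth, unmeth)


def _groups(n1, n2):
    return {f"S{i + 1}": ("group1" if i < n1 else "group2")
            for i in range(n1 + n2)}


def test_coverage_exactly_ten_is_removed():
    # the coverage filter is strictly "> 10"
    m = _uniform_matrix(10)
    out = ml.filter_sites(m, _groups(12, 12))
    assert len(out) == 0
    assert len(ml.filter_sites(_uniform_matrix(11), _groups(12, 12))) == 1


def test_sex_chromosome_sites_removed_regardless_of_coverage():
    m = _uniform_matrix(100, chrom="chrX")
    assert len(ml.filter_sites(m, _groups(12, 12))) == 0


def test_boundary_site_in_ten_samples_per_group_retained():
    # covered (>10 reads) in exactly 10 samples of each 12-sample group
    per_sample = [20] * 10 + [5] * 2 + [20] * 10 + [5] * 2
    m = make_matrix({"chr1:100": [c // 2 for c in per_sample]},
                    {"chr1:100": [c - c // 2 for c in per_sample]})
    assert len(ml.filter_sites(m, _groups(12, 12))) == 1
    nine = [20] * 9 + [5] * 3 + [20] * 10 + [5] * 2
    m9 = make_matrix({"chr1:100": [c // 2 for c in nine]},
                     {"chr1:100": [c - c // 2 for c in nine]})
    assert len(ml.filter_sites(m9, _groups(12, 12))) == 0


def test_group_smaller_than_min_per_group_is_config_error():
    m = _uniform_matrix(20, n_samples=12)
    with pytest.raises(MethylationError, match="min_per_group"):
        ml.filter_sites(m, _groups(4, 8))


def test_retained_sites_satisfy_rule_by_recount(small_methylome):
    matrix, groups, _ = small_methylome
    out = ml.filter_sites(matrix, groups)
    cov = out.coverage
    g1 = [s for s in cov.columns if groups[s] == "group1"]
    g2 = [s for s in cov.columns if groups[s] == "group2"]
    assert ((cov[g1] > 10).sum(axis=1) >= 10).all()
    assert ((cov[g2] > 10).sum(axis=1) >= 10).all()


# ---------------------------------------------------------------- testing

def test_identical_counts_give_zero_diff_and_p_one():
    m = make_matrix({"chr1:100": [5] * 20}, {"chr1:100": [5] * 20})
    res = ml.test_dm(m, _groups(10, 10))
    assert res["meth_diff"].iloc[0] == pytest.approx(0.0)
    assert res["p_value"].iloc[0] == pytest.approx(1.0)


def test_strong_effect_matches_fisher_oracle():
    # group1 all 9/1, group2 all 1/9: diff +80 points, p < 1e-6 for both
    # the logistic LRT and the pooled 2x2 Fisher cross-check
    m = make_matrix({"chr1:100": [9] * 10 + [1] * 10},
                    {"chr1:100": [1] * 10 + [9] * 10})
    res = ml.test_dm(m, _groups(10, 10))
    assert res["meth_diff"].iloc[0] == pytest.approx(80.0)
    assert res["p_value"].iloc[0] < 1e-6
    fisher = ml.test_dm(m, _groups(10, 10), method="fisher")
    assert fisher["p_value"].iloc[0] < 1e-6


def test_lrt_matches_statsmodels_glm(rng):
    """The closed-form LRT equals an iteratively fitted binomial GLM."""
    import statsmodels.api as sm

    for _ in range(10):
        c = rng.integers(0, 30, size=12)
        t = rng.integers(1, 30, size=12)
        group = np.repeat([0, 1], 6)
        closed = _binomial_lrt(c[:6].sum(), t[:6].sum(),
                               c[6:].sum(), t[6:].sum())
        endog = np.column_stack([c, t])
        full = sm.GLM(endog, sm.add_constant(group),
                      family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones_like(group, dtype=float),
                      family=sm.families.Binomial()).fit()
        stat = 2 * (full.llf - null.llf)
        assert closed == pytest.approx(stats.chi2.sf(max(stat, 0), 1), abs=1e-8)


def test_null_beta_binomial_type_one_error():
    cfg = ml.SimulationConfig(n_samples_per_group=20, n_genes=40, n_cpgs=2000,
                              frac_dm_cpgs=0.0, seed=5)
    genes, islands = ml.generate_annotation(cfg)
    meth, unmeth, sites, _ = ml.simulate_methylation(cfg, genes, islands)
    _, groups = sample_ids(cfg)
    mat = ml.CpGCountMatrix(meth, unmeth, sites)
    res = ml.test_dm(ml.filter_sites(mat, groups), groups)
    frac = (res["p_value"] < 0.05).mean()
    assert 0.025 <= frac <= 0.085


def test_group_label_swap_negates_diffs(small_methylome):
    matrix, groups, _ = small_methylome
    filt = ml.filter_sites(matrix, groups)
    res = ml.test_dm(filt, groups)
    swapped = {s: ("group2" if g == "group1" else "group1")
               for s, g in groups.items()}
    res_sw = ml.test_dm(filt, swapped)
    assert np.allclose(res["meth_diff"], -res_sw["meth_diff"])
    res["q_value"] = ml.adjust_bh(res["p_value"].values)
    res_sw["q_value"] = ml.adjust_bh(res_sw["p_value"].values)
    d1, d2 = ml.call_dmcs(res), ml.call_dmcs(res_sw)
    assert (d1["direction"] == "hyper").sum() == (d2["direction"] == "hypo").sum()
    assert (d1["direction"] == "hypo").sum() == (d2["direction"] == "hyper").sum()


# ---------------------------------------------------------------- BH

def test_bh_worked_examples():
    assert ml.adjust_bh([0.03]) == pytest.approx([0.03])
    assert ml.adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert ml.adjust_bh([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        ml.adjust_bh([0.5, 1.5])
    with pytest.raises(ValueError):
        ml.adjust_bh([-0.1])


def test_bh_matches_statsmodels_and_properties(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(25):
        p = rng.uniform(size=int(rng.integers(1, 200)))
        q = ml.adjust_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------- calling

def test_dmc_thresholds_are_strict():
    res = pd.DataFrame({
        "chrom": ["chr1"] * 3, "pos": [1, 2, 3],
        "meth_diff": [14.9, -20.0, 16.0],
        "p_value": [1e-5, 1e-5, 1e-5],
        "q_value": [0.001, 0.005, 0.01],
    }, index=["a", "b", "c"])
    dmcs = ml.call_dmcs(res)
    # 14.9 fails the strict ">15" rule; q exactly 0.01 fails "<0.01"
    assert list(dmcs.index) == ["b"]
    assert dmcs.loc["b", "direction"] == "hypo"


def test_hyper_hypo_partition(small_methylome):
    matrix, groups, _ = small_methylome
    res = ml.test_dm(ml.filter_sites(matrix, groups), groups)
    res["q_value"] = ml.adjust_bh(res["p_value"].values)
    dmcs = ml.call_dmcs(res)
    n_hyper = (dmcs["direction"] == "hyper").sum()
    n_hypo = (dmcs["direction"] == "hypo").sum()
    assert n_hyper + n_hypo == len(dmcs)
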