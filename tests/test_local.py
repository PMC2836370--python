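import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methcna.local import (
    correlation_screen,
    flag_significant,
    gene_aggregate,
    match_loci,
    qvalues,
)


def _annot(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "locus", "gene", "upstream"])


def test_match_nearest_snp():
    cpg = _annot([("chr1", 100, "cg1", "G1", 1)])
    snp = _annot([("chr1", 90, "s1", None, np.nan), ("chr1", 150, "s2", None, np.nan)])
    out = match_loci(cpg, snp)
    assert out.loc[0, "snp"] == "s1" and out.loc[0, "distance"] == 10


def test_match_tie_goes_to_lower_coordinate():
    cpg = _annot([("chr1", 100, "cg1", "G1", 1)])
    snp = _annot([("chr1", 90, "s1", None, np.nan), ("chr1", 110, "s2", None, np.nan)])
    out = match_loci(cpg, snp)
    assert out.loc[0, "snp"] == "s1"


def test_match_flags_chromosome_without_snps_and_max_distance():
    cpg = _annot([("chr2", 100, "cg1", "G1", 1), ("chr1", 0, "cg2", "G2", 1)])
    snp = _annot([("chr1", 5000, "s1", None, np.nan)])
    out = match_loci(cpg, snp, max_distance=1000).set_index("cpg")
    assert out.loc["cg1", "flag"] == "no SNP on chromosome"
    assert out.loc["cg2", "flag"] == "beyond max_distance"


def test_match_equals_brute_force_oracle(rng):
    chroms = [f"chr{i}" for i in range(1, 4)]
    cpg = _annot(
        [(rng.choice(chroms), int(rng.integers(0, 10**6)), f"cg{i}", None, 1)
         for i in range(300)]
    )
    snp = _annot(
        [(rng.choice(chroms), int(rng.integers(0, 10**6)), f"s{i}", None, np.nan)
         for i in range(700)]
    )
    got = match_loci(cpg, snp).set_index("cpg")
    for _, row in cpg.iterrows():
        cands = snp[snp["chrom"] == row["chrom"]]
        d = (cands["start"] - row["start"]).abs()
        best = d.min()
        # oracle tie rule: smallest distance, then lowest coordinate
        winners = cands.loc[d == best].sort_values("start")
        assert got.loc[row["locus"], "snp"] == winners["locus"].iloc[0]
        assert got.loc[row["locus"], "distance"] == best


def _beta(rows, cols, vals):
    return pd.DataFrame(vals, index=rows, columns=cols, dtype=float)


def test_gene_aggregate_promoter_mean_and_filters():
    cpg = _annot(
        [
            ("chr1", 100, "cg1", "G1", 1),
            ("chr1", 150, "cg2", "G1", 1),
            ("chr1", 300, "cg3", "G2", 0),  # downstream only -> G2 excluded
        ]
    )
    snp = _annot([("chr1", 120, "s1", "G1", np.nan), ("chr1", 140, "s2", "G1", np.nan)])
    beta = _beta(["cg1", "cg2", "cg3"], ["T1"], [[0.2], [0.4], [0.9]])
    cn = pd.DataFrame({"T1": [2, 4]}, index=["s1", "s2"], dtype=float)
    gb, gc = gene_aggregate(beta, cn, cpg, snp)
    assert gb.loc["G1", "T1"] == pytest.approx(0.3)
    assert "G2" not in gb.index
    assert gc.loc["G1", "T1"] == pytest.approx(3.0)


def test_gene_aggregate_matches_loop_oracle(rng, small_cohort):
    c = small_cohort
    gb, gc = gene_aggregate(c.beta, c.cn_states, c.cpg_annotation, c.snp_annotation)
    genes = rng.choice(gb.index.to_numpy(), size=10, replace=False)
    for g in genes:
        cpgs = c.cpg_annotation.query("gene == @g and upstream == 1")["locus"]
        expected = c.beta.loc[cpgs].mean(axis=0)
        assert np.allclose(gb.loc[g], expected.loc[gb.columns])
    for g in rng.choice(gc.index.to_numpy(), size=10, replace=False):
        snps = c.snp_annotation.query("gene == @g")["locus"]
        expected = c.cn_states.loc[snps].mean(axis=0)
        assert np.allclose(gc.loc[g], expected.loc[gc.columns])


def test_correlation_hand_example():
    x = _beta(["u1"], list("abcde"), [[1, 2, 3, 4, 5]])
    y = _beta(["u1"], list("abcde"), [[2, 1, 4, 3, 5]])
    out = correlation_screen(x, y, n_perm=200, seed=0)
    assert out.loc[0, "r"] == pytest.approx(0.8, abs=1e-12)


def test_perfect_correlation_hits_p_floor(rng):
    vals = rng.uniform(0, 1, size=(1, 19))
    x = _beta(["u1"], [f"T{i}" for i in range(19)], vals)
    out = correlation_screen(x, x.copy(), n_perm=5000, seed=0)
    assert out.loc[0, "r"] == pytest.approx(1.0)
    assert out.loc[0, "p"] == pytest.approx(1.0 / 5001.0)


def test_zero_variance_unit_excluded():
    x = _beta(["u1"], list("abcd"), [[0.1, 0.2, 0.3, 0.4]])
    y = _beta(["u1"], list("abcd"), [[2.0, 2.0, 2.0, 2.0]])
    out = correlation_screen(x, y, n_perm=50, seed=0)
    assert out.loc[0, "flag"] == "zero variance"
    assert np.isnan(out.loc[0, "r"])


def test_correlation_r_matches_scipy(rng):
    from scipy.stats import pearsonr

    x = _beta([f"u{i}" for i in range(20)], [f"T{i}" for i in range(15)],
              rng.uniform(0, 1, size=(20, 15)))
    y = _beta(x.index, x.columns, rng.uniform(0, 5, size=(20, 15)))
    out = correlation_screen(x, y, n_perm=10, seed=0).set_index("unit")
    for u in x.index:
        assert out.loc[u, "r"] == pytest.approx(
            pearsonr(x.loc[u], y.loc[u]).statistic, abs=1e-12
        )


def test_permutation_p_uniform_under_null(rng):
    from scipy.stats import kstest

    x = _beta([f"u{i}" for i in range(1000)], [f"T{i}" for i in range(19)],
              rng.uniform(0, 1, size=(1000, 19)))
    y = _beta(x.index, x.columns, rng.normal(2, 1, size=(1000, 19)))
    out = correlation_screen(x, y, n_perm=200, seed=1)
    assert kstest(out["p"], "uniform").pvalue > 0.01


def test_qvalues_all_ones():
    assert (qvalues(np.ones(50)) == 1.0).all()


def test_qvalues_bh_equivalence_with_few_pvalues():
    # < 10 p-values: pi0 falls back to 1 => exactly Benjamini-Hochberg
    from statsmodels.stats.multitest import multipletests

    p = np.array([0.01, 0.04, 0.03, 0.2, 0.5, 0.9, 0.7, 0.02])
    with pytest.warns(UserWarning, match="pi0 = 1"):
        q = qvalues(p)
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, bh, atol=1e-12)


def test_qvalues_scale_as_pi0_times_bh(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(0.0001, 1, size=200)
    q = qvalues(p)
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    ratio = q / bh
    # one shared pi0 factor in (0, 1]
    assert np.allclose(ratio, ratio[0], atol=1e-10)
    assert 0 < ratio[0] <= 1.0


@given(st.lists(st.floats(1e-6, 1.0), min_size=12, max_size=60))
@settings(max_examples=100, derandomize=True)
def test_qvalues_monotone_in_p(pvals):
    p = np.array(pvals)
    q = qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_qvalues_reject_invalid():
    with pytest.raises(ValueError):
        qvalues(np.array([0.0, 0.5]))
    with pytest.raises(ValueError):
        qvalues(np.array([0.5, 1.5]))


def test_flag_significant_sorting_and_empty():
    empty = pd.DataFrame(columns=["unit", "r", "p", "q"])
    assert flag_significant(empty).empty
    res = pd.DataFrame(
        {
            "unit": ["a", "b", "c", "d"],
            "r": [0.5, -0.9, 0.7, 0.2],
            "p": [0.001, 0.0005, 0.0005, 0.5],
            "q": [0.01, 0.01, 0.01, 0.6],
        }
    )
    out = flag_significant(res, 0.05)
    assert list(out["unit"]) == ["b", "c", "a"]  # ties by |r| descending


def test_correlation_screen_pairwise_complete_handling(rng):
    x = _beta([f"u{i}" for i in range(5)], [f"T{i}" for i in range(12)],
              rng.uniform(0, 1, size=(5, 12)))
    y = _beta(x.index, x.columns, rng.normal(2, 1, size=(5, 12)))
    x.iloc[0, :3] = np.nan          # unit with 9 complete pairs
    x.iloc[1, :10] = np.nan         # unit with 2 complete pairs -> excluded
    out = correlation_screen(x, y, n_perm=100, seed=0)
    assert out.loc[0, "n"] == 9 and 0 < out.loc[0, "p"] <= 1
    assert out.loc[1, "flag"] == "fewer than 3 complete pairs"
    from scipy.stats import pearsonr

    m = x.iloc[0].notna()
    assert out.loc[0, "r"] == pytest.approx(
        pearsonr(x.iloc[0][m], y.iloc[0][m]).statistic, abs=1e-12
    )
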