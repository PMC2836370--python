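import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from methcna.cluster import (
    cut_k,
    dichotomize_cna,
    export_orderings,
    hamming_matrix,
    line1_group_difference,
    ward_cluster,
)


def test_hamming_identical_and_example():
    df = pd.DataFrame(
        {"A": [2, 2, 0, 4], "B": [2, 2, 0, 4], "C": [2, 3, 0, 2]}
    )
    D = hamming_matrix(df)
    assert D.loc["A", "B"] == 0.0
    assert D.loc["A", "C"] == 2.0


def test_hamming_matches_loop_oracle(rng):
    states = rng.integers(0, 5, size=(60, 15))
    df = pd.DataFrame(states, columns=[f"T{i}" for i in range(15)])
    D = hamming_matrix(df)
    for i in range(15):
        for j in range(15):
            expected = int((states[:, i] != states[:, j]).sum())
            assert D.iloc[i, j] == expected


def test_hamming_missing_rescaled():
    df = pd.DataFrame({"A": [2, 0, np.nan, 4], "B": [2, 2, 2, 2]})
    D = hamming_matrix(df)
    # 2 mismatches over 3 co-observed loci, rescaled to 4
    assert D.loc["A", "B"] == pytest.approx(2 * 4 / 3)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, derandomize=True)
def test_hamming_is_a_metric_on_complete_vectors(seed):
    r = np.random.default_rng(seed)
    df = pd.DataFrame(r.integers(0, 5, size=(20, 3)), columns=list("xyz"))
    D = hamming_matrix(df).to_numpy()
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0)
    assert D[0, 1] <= D[0, 2] + D[2, 1] + 1e-9


def test_ward_duplicated_samples_merge_first():
    df = pd.DataFrame({"A": [1, 2, 3], "B": [1, 2, 3], "C": [9, 9, 9]})
    X = df.T.to_numpy(dtype=float)
    D = pd.DataFrame(squareform(pdist(X)), index=df.columns, columns=df.columns)
    dend = ward_cluster(D, metric="euclidean")
    assert dend.merges[0, 2] == 0.0
    assert {int(dend.merges[0, 0]), int(dend.merges[0, 1])} == {0, 1}


def test_ward_heights_match_scipy(rng):
    X = rng.normal(size=(12, 5))
    D = squareform(pdist(X))
    dend = ward_cluster(pd.DataFrame(D), metric="euclidean")
    ref = linkage(pdist(X), method="ward")
    assert np.allclose(np.sort(dend.merges[:, 2]), np.sort(ref[:, 2]), atol=1e-8)


def test_ward_rejects_asymmetric():
    with pytest.raises(ValueError):
        ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_ward_recovers_planted_blocks(rng):
    # two blocks with small within- and large between-distances
    n = 8
    D = np.full((n, n), 50.0)
    for blk in (range(4), range(4, 8)):
        for i in blk:
            for j in blk:
                D[i, j] = 0.0 if i == j else rng.uniform(1, 3)
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    dend = ward_cluster(pd.DataFrame(D))
    labels = cut_k(dend, 2)
    assert len(set(labels.iloc[:4])) == 1
    assert len(set(labels.iloc[4:])) == 1
    assert labels.iloc[0] != labels.iloc[-1]


def test_newick_and_leaf_order_cover_all_leaves():
    df = pd.DataFrame(np.eye(4) * 3 + 2, columns=list("abcd"))
    dend = ward_cluster(hamming_matrix(df))
    order = dend.leaf_order()
    assert sorted(order) == list("abcd")
    nwk = dend.to_newick()
    assert nwk.endswith(";") and all(leaf in nwk for leaf in "abcd")


def test_dichotomize_high_is_larger_burden():
    D = np.array(
        [
            [0, 1, 40, 40],
            [1, 0, 40, 40],
            [40, 40, 0, 1],
            [40, 40, 1, 0],
        ],
        dtype=float,
    )
    dend = ward_cluster(pd.DataFrame(D, index=list("abcd"), columns=list("abcd")))
    burden = pd.Series([0.5, 0.6, 0.01, 0.02], index=list("abcd"))
    groups = dichotomize_cna(dend, burden)
    assert (groups[["a", "b"]] == "high").all()
    assert (groups[["c", "d"]] == "low").all()


def test_dichotomize_order_invariance(rng, small_cohort):
    from methcna.hmm import burden as burden_fn

    cn = small_cohort.cn_states
    b = burden_fn(cn)
    base = dichotomize_cna(ward_cluster(hamming_matrix(cn)), b)
    perm = rng.permutation(cn.shape[1])
    shuffled = cn.iloc[:, perm]
    other = dichotomize_cna(ward_cluster(hamming_matrix(shuffled)), b.iloc[perm])
    assert (other.loc[base.index] == base).all()


def test_line1_difference_hand_example():
    line1 = pd.Series([50.0, 52.0, 64.0, 66.0], index=list("abcd"))
    groups = pd.Series(["high", "high", "low", "low"], index=list("abcd"))
    out = line1_group_difference(line1, groups)
    assert out["difference"] == pytest.approx(-14.0)
    # Welch CI recomputed independently
    from scipy import stats

    se = np.sqrt(2.0 / 2 + 2.0 / 2)  # both variances are 2
    df = (1 + 1) ** 2 / (1.0 / 1 + 1.0 / 1)  # Satterthwaite: 2
    t = stats.t.ppf(0.975, df)
    assert out["ci_low"] == pytest.approx(-14 - t * se, abs=1e-9)
    assert out["ci_high"] == pytest.approx(-14 + t * se, abs=1e-9)


def test_line1_identical_groups_ci_contains_zero():
    line1 = pd.Series([60.0, 61.0, 60.0, 61.0], index=list("abcd"))
    groups = pd.Series(["high", "high", "low", "low"], index=list("abcd"))
    out = line1_group_difference(line1, groups)
    assert out["difference"] == 0.0
    assert out["ci_low"] < 0 < out["ci_high"]


def test_line1_singleton_group_gives_point_estimate_only():
    line1 = pd.Series([60.0, 50.0, 52.0], index=list("abc"))
    groups = pd.Series(["high", "low", "low"], index=list("abc"))
    out = line1_group_difference(line1, groups)
    assert out["ci_available"] is False
    assert out["difference"] == pytest.approx(60 - 51)


def test_orderings_are_permutations(small_cohort):
    from methcna.hmm import burden as burden_fn
    from methcna.rpmm import rpmm_fit

    c = small_cohort
    tumors = list(c.tumors)
    classing = rpmm_fit(c.beta[tumors].T, seed=0)
    dend = ward_cluster(hamming_matrix(c.cn_states[tumors]))
    orderings = export_orderings(classing.to_frame(), c.beta[tumors], dend)
    assert sorted(orderings["methylation"]) == sorted(tumors)
    assert sorted(orderings["copy_number"]) == sorted(tumors)
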