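import numpy as np
import pandas as pd
import pytest

from methcna.rpmm import (
    _clamp,
    _em,
    fit_beta_mixture,
    root_grouping,
    rpmm_fit,
    weighted_beta_mle,
)
from methcna.simulate import SimulationConfig, simulate_cohort


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(np.asarray(a), np.asarray(b))


def test_single_component_parameter_recovery(rng):
    # 500 draws from Beta(5, 2): weighted MLE within 15% of truth
    x = rng.beta(5.0, 2.0, size=(500, 1))
    a, b = weighted_beta_mle(_clamp(x), np.ones(500))
    assert abs(a[0] - 5.0) / 5.0 < 0.15
    assert abs(b[0] - 2.0) / 2.0 < 0.15


def test_weighted_mle_solves_score_equations(rng):
    from scipy.special import digamma

    x = _clamp(rng.beta(2.0, 7.0, size=(200, 5)))
    w = rng.uniform(0.2, 1.0, size=200)
    a, b = weighted_beta_mle(x, w)
    W = w.sum()
    pbar = w @ np.log(x) / W
    qbar = w @ np.log1p(-x) / W
    assert np.allclose(digamma(a) - digamma(a + b), pbar, atol=1e-6)
    assert np.allclose(digamma(b) - digamma(a + b), qbar, atol=1e-6)


def test_two_separated_components_recovered(rng):
    # means 0.2 vs 0.8 at every CpG: hard assignment must match generators
    n, p = 20, 30
    X = np.vstack(
        [rng.beta(0.2 * 40, 0.8 * 40, size=(10, p)),
         rng.beta(0.8 * 40, 0.2 * 40, size=(10, p))]
    )
    _, _, _, resp, _ = fit_beta_mixture(X, K=2, seed=0)
    hard = resp.argmax(axis=1)
    assert len(set(hard[:10])) == 1 and len(set(hard[10:])) == 1
    assert hard[0] != hard[-1]


def test_em_loglik_is_non_decreasing(rng):
    X = _clamp(rng.beta(2, 2, size=(15, 10)))
    w = np.ones(15)
    r0 = rng.dirichlet(np.ones(2), size=15)
    lls = []
    for iters in range(1, 12):
        out = _em(X, w, r0.copy(), tol=0.0, max_iter=iters)
        assert out is not None
        lls.append(out[-1])
    assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


def test_homogeneous_data_gives_single_class(rng):
    X = rng.beta(3.0, 3.0, size=(24, 40))
    classing = rpmm_fit(X, max_depth=3, seed=0)
    assert classing.n_leaves == 1
    assert (classing.leaf_labels == 1).all()


def test_depth_cap_limits_class_count():
    cfg = SimulationConfig(
        n_tumors=40, n_normals=2, n_cpg=200, n_genes=100, n_snp=300,
        n_classes=4, beta_precision=100.0, class_burden_targets=[0.05] * 4,
        seed=3,
    )
    cohort = simulate_cohort(cfg)
    X = cohort.beta[list(cohort.tumors)].T
    classing = rpmm_fit(X, max_depth=1, seed=3)
    assert classing.n_leaves <= 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_four_class_recovery(seed):
    # well-separated 4-class cohorts: leaves recover the planted classes
    cfg = SimulationConfig(
        n_tumors=40, n_normals=2, n_cpg=200, n_genes=100, n_snp=300,
        n_classes=4, beta_precision=100.0, class_burden_targets=[0.05] * 4,
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    X = cohort.beta[list(cohort.tumors)].T
    classing = rpmm_fit(X, max_depth=3, seed=seed)
    assert classing.n_leaves == 4
    truth = cohort.truth.class_labels
    assert _ari(truth, classing.leaf_labels.loc[truth.index]) >= 0.9


def test_root_grouping_separates_super_groups():
    # classes {1,2} vs {3,4} are the most distinct super-groups by design
    hits = 0
    for seed in range(5):
        cfg = SimulationConfig(
            n_tumors=40, n_normals=2, n_cpg=200, n_genes=100, n_snp=300,
            n_classes=4, beta_precision=100.0,
            class_burden_targets=[0.05] * 4, seed=seed,
        )
        cohort = simulate_cohort(cfg)
        classing = rpmm_fit(cohort.beta[list(cohort.tumors)].T, seed=seed)
        side = root_grouping(classing)
        truth = cohort.truth.class_labels
        agree = ((truth <= 2) == (side.loc[truth.index] == "left")).mean()
        hits += max(agree, 1.0 - agree) == 1.0
    assert hits >= 4


def test_two_class_grouping_equals_leaf_classes(rng):
    n, p = 20, 40
    X = np.vstack(
        [rng.beta(0.15 * 50, 0.85 * 50, size=(10, p)),
         rng.beta(0.85 * 50, 0.15 * 50, size=(10, p))]
    )
    classing = rpmm_fit(X, max_depth=1, seed=0)
    assert classing.n_leaves == 2
    side = root_grouping(classing)
    # depth-1 tree: leaf class and root side carry the same partition
    mapping = pd.crosstab(classing.leaf_labels, side)
    assert (mapping.to_numpy() > 0).sum() == 2


def test_unsplit_root_warns_and_labels_all_left(rng):
    X = rng.beta(3.0, 3.0, size=(10, 20))
    classing = rpmm_fit(X, max_depth=2, seed=0)
    assert classing.n_leaves == 1
    with pytest.warns(UserWarning, match="root split"):
        side = root_grouping(classing)
    assert (side == "left").all()


def test_sample_order_invariance_on_separated_data(rng):
    n, p = 24, 40
    X = np.vstack(
        [rng.beta(0.2 * 60, 0.8 * 60, size=(12, p)),
         rng.beta(0.8 * 60, 0.2 * 60, size=(12, p))]
    )
    df = pd.DataFrame(X, index=[f"S{i}" for i in range(n)])
    base = rpmm_fit(df, seed=5).leaf_labels
    perm = rng.permutation(n)
    shuffled = rpmm_fit(df.iloc[perm], seed=5).leaf_labels
    assert (shuffled.loc[base.index] == base).all()


def test_accepted_split_strictly_decreases_bic():
    cfg = SimulationConfig(
        n_tumors=40, n_normals=2, n_cpg=200, n_genes=100, n_snp=300,
        n_classes=2, beta_precision=60.0, class_burden_targets=[0.05] * 2,
        seed=11,
    )
    cohort = simulate_cohort(cfg)
    classing = rpmm_fit(cohort.beta[list(cohort.tumors)].T, seed=11)

    def check(node):
        if node.split_accepted:
            assert node.bic2 < node.bic1
            for child in node.children:
                check(child)

    assert classing.root.split_accepted
    check(classing.root)
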