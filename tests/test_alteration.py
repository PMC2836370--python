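import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcna.alteration import cn_alteration, methylation_alteration, stratified_volcano


def _frame(vals, prefix):
    vals = np.atleast_2d(np.asarray(vals, dtype=float))
    return pd.DataFrame(
        vals,
        index=[f"u{i}" for i in range(vals.shape[0])],
        columns=[f"{prefix}{j}" for j in range(vals.shape[1])],
    )


def test_identical_groups_give_t0_p1():
    t = _frame([[0.5, 0.5, 0.5]], "T")
    n = _frame([[0.5, 0.5, 0.5]], "N")
    out = methylation_alteration(t, n)
    assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0


def test_welch_t_matches_textbook_formula():
    tumor = np.array([0.8, 0.9, 0.7])
    normal = np.array([0.1, 0.2, 0.15])
    out = methylation_alteration(_frame([tumor], "T"), _frame([normal], "N"))
    # independent Welch computation
    vt, vn = tumor.var(ddof=1), normal.var(ddof=1)
    se = np.sqrt(vt / 3 + vn / 3)
    t_exp = (tumor.mean() - normal.mean()) / se
    df_exp = (vt / 3 + vn / 3) ** 2 / ((vt / 3) ** 2 / 2 + (vn / 3) ** 2 / 2)
    p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
    assert out.loc[0, "t"] == pytest.approx(t_exp, abs=1e-10)
    assert out.loc[0, "p"] == pytest.approx(p_exp, abs=1e-10)
    assert out.loc[0, "mean_alteration"] == pytest.approx(0.8 - 0.15, abs=1e-12)


def test_t_sign_matches_mean_alteration(rng):
    t = _frame(rng.uniform(0, 1, size=(40, 6)), "T")
    n = _frame(rng.uniform(0, 1, size=(40, 5)), "N")
    out = methylation_alteration(t, n)
    ok = out["t"].notna() & (out["t"] != 0)
    assert (np.sign(out.loc[ok, "t"]) == np.sign(out.loc[ok, "mean_alteration"])).all()


def test_null_calibration_of_welch_test(rng):
    # same beta law in both groups at 663 units
    t = _frame(rng.beta(2, 5, size=(663, 19)), "T")
    n = _frame(rng.beta(2, 5, size=(663, 11)), "N")
    out = methylation_alteration(t, n)
    frac = (out["p"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07


def test_one_sample_t_closed_form():
    vals = [3, 3, 3, 2, 2, 2, 2, 2, 2]
    out = cn_alteration(_frame([vals], "T"))
    assert out.loc[0, "t"] == pytest.approx(2.0, abs=1e-12)
    assert out.loc[0, "mean_alteration"] == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_all_diploid_gene_gives_t0_p1():
    out = cn_alteration(_frame([[2, 2, 2, 2]], "T"))
    assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0


def test_degenerate_zero_variance_off_null_excluded():
    out = cn_alteration(_frame([[3, 3, 3, 3]], "T"))
    assert out.loc[0, "flag"].startswith("degenerate")
    assert np.isnan(out.loc[0, "p"])


def test_neg_log10_p_consistent_with_p(rng):
    t = _frame(rng.uniform(0, 1, size=(50, 8)), "T")
    n = _frame(rng.uniform(0, 1, size=(50, 8)), "N")
    out = methylation_alteration(t, n)
    ok = out["p"].notna()
    assert np.allclose(
        out.loc[ok, "neg_log10_p"], -np.log10(out.loc[ok, "p"]), atol=1e-12
    )


def test_stratified_volcano_partitions_tumors(rng):
    tumors = [f"T{i}" for i in range(12)]
    gb_t = pd.DataFrame(rng.uniform(0, 1, size=(30, 12)),
                        index=[f"g{i}" for i in range(30)], columns=tumors)
    gb_n = pd.DataFrame(rng.uniform(0, 1, size=(30, 6)),
                        index=gb_t.index, columns=[f"N{i}" for i in range(6)])
    gc = pd.DataFrame(rng.integers(0, 5, size=(30, 12)).astype(float),
                      index=gb_t.index, columns=tumors)
    side = pd.Series(["left"] * 7 + ["right"] * 5, index=tumors)
    out = stratified_volcano(gb_t, gb_n, gc, side)
    assert set(out["stratum"]) == {"all", "left", "right"}
    assert set(out["type"]) == {"methylation", "copy_number"}
    # identical inputs => the 'all' stratum equals recomputation on all tumors
    direct = methylation_alteration(gb_t, gb_n)
    got = out[(out["stratum"] == "all") & (out["type"] == "methylation")]
    assert np.allclose(got["p"].to_numpy(), direct["p"].to_numpy(), equal_nan=True)


def test_small_stratum_skipped(rng):
    tumors = [f"T{i}" for i in range(5)]
    gb_t = pd.DataFrame(rng.uniform(0, 1, size=(10, 5)),
                        index=[f"g{i}" for i in range(10)], columns=tumors)
    gb_n = pd.DataFrame(rng.uniform(0, 1, size=(10, 4)),
                        index=gb_t.index, columns=[f"N{i}" for i in range(4)])
    gc = pd.DataFrame(rng.integers(0, 5, size=(10, 5)).astype(float),
                      index=gb_t.index, columns=tumors)
    side = pd.Series(["left"] * 4 + ["right"], index=tumors)
    out = stratified_volcano(gb_t, gb_n, gc, side)
    assert "right" not in set(out["stratum"])  # singleton stratum skipped


def test_cn_significants_concentrate_in_high_burden_stratum():
    # two classes, one carrying all the CNA: the root-side stratum holding
    # the high-burden tumors accumulates the copy-number significants
    from methcna.local import gene_aggregate
    from methcna.rpmm import rpmm_fit
    from methcna.simulate import SimulationConfig, simulate_cohort

    ratios = []
    for seed in range(3):
        cfg = SimulationConfig(
            n_tumors=20, n_normals=6, n_cpg=200, n_genes=100, n_snp=2000,
            n_classes=2, class_burden_targets=[0.5, 0.0], beta_precision=60.0,
            seed=seed,
        )
        c = simulate_cohort(cfg)
        tumors = list(c.tumors)
        gb, gc = gene_aggregate(c.beta, c.cn_states, c.cpg_annotation,
                                c.snp_annotation)
        classing = rpmm_fit(c.beta[tumors].T, seed=seed)
        out = stratified_volcano(
            gb[tumors], gb[[x for x in c.normals if x in gb.columns]],
            gc[[t for t in tumors if t in gc.columns]], classing.root_side,
        )
        # the stratum holding the high-burden class
        high_class = c.truth.class_labels[c.truth.class_labels == 1].index
        side_of_high = classing.root_side.loc[high_class].mode()[0]
        cn = out[(out["type"] == "copy_number") & out["significant"]]
        n_high = (cn["stratum"] == side_of_high).sum()
        other = "left" if side_of_high == "right" else "right"
        n_other = (cn["stratum"] == other).sum()
        ratios.append((n_high, n_other))
    assert all(h >= 5 * max(o, 1) or (h > 0 and o == 0) for h, o in ratios), ratios
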