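"""Reference experiments: the cohort-level computations behind the
headline results, with simulation scales chosen to run in seconds to
minutes on one CPU.

Each function simulates under the documented study conditions (19 tumors,
11 normals, K=5 methylation classes with two high-burden classes at
target burden 0.5 and the rest at 0.05 unless stated otherwise), runs the
corresponding analysis through the package, and returns the measured
quantities. They are used by the numbered analysis drivers, the
acceptance tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .cluster import dichotomize_cna, hamming_matrix, line1_group_difference, ward_cluster
from .global_test import permutation_test_global
from .hmm import CNHmmModel, burden, call_state_matrix
from .local import correlation_screen, gene_aggregate
from .preprocess import line1_summary
from .rpmm import rpmm_fit
from .simulate import SimulationConfig, plant_local_coupling, simulate_cohort

__all__ = [
    "headline_global_test",
    "null_calibration",
    "local_screen_characteristics",
    "rpmm_recovery",
    "hmm_recovery",
    "line1_analysis",
    "line1_ci_coverage",
]


def headline_global_test(seed: int, n_snp: int = 5000, n_perm: int = 10000) -> dict:
    """Class/burden permutation Kruskal-Wallis test on the default cohort.

    19 tumors in 5 classes, two classes at burden target 0.5, three at
    0.05; 10,000 label permutations.
    """
    cfg = SimulationConfig(n_snp=n_snp, seed=seed)
    cohort = simulate_cohort(cfg)
    res = permutation_test_global(
        cohort.truth.true_burden,
        cohort.truth.class_labels,
        n_perm=n_perm,
        seed=stage_rng(seed, "headline/perm"),
    )
    return {"H": res.H, "p": res.p, "n_perm": n_perm, "n_snp": n_snp}


def null_calibration(
    seed: int,
    n_cohorts: int = 1000,
    n_snp: int = 500,
    n_perm: int = 499,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the global test under kappa=0 (no coupling).

    Reduced cohorts (500 SNP loci); the rejection rate at ``alpha``
    should sit near ``alpha``.
    """
    rejections = 0
    for i in range(n_cohorts):
        cfg = SimulationConfig(
            n_cpg=40, n_genes=20, n_snp=n_snp, kappa=0.0,
            seed=int(stage_rng(seed, f"nullcal/{i}").integers(2**31)),
        )
        cohort = simulate_cohort(cfg)
        res = permutation_test_global(
            cohort.truth.true_burden,
            cohort.truth.class_labels,
            n_perm=n_perm,
            seed=stage_rng(seed, f"nullcal/perm/{i}"),
        )
        rejections += res.p <= alpha
    return {
        "rejection_rate": rejections / n_cohorts,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
    }


def _gene_screen(cohort, n_perm, seed):
    gb, gc = gene_aggregate(
        cohort.beta, cohort.cn_states, cohort.cpg_annotation, cohort.snp_annotation
    )
    tumors = list(cohort.tumors)
    shared = gb.index.intersection(gc.index)
    return correlation_screen(
        gb.loc[shared, tumors], gc.loc[shared, tumors], n_perm=n_perm,
        seed=seed, level="gene",
    )


def local_screen_characteristics(
    seed: int,
    n_seeds: int = 12,
    n_genes: int = 200,
    n_cpg: int = 400,
    n_snp: int = 5000,
    n_planted: int = 10,
    target_r: float = 0.95,
    n_perm: int = 5000,
    q_threshold: float = 0.05,
) -> dict:
    """False-positive rate and power of the gene-level correlation screen.

    FPR: cohorts with global coupling only (kappa=1, no planted genes) —
    the fraction of genes reaching q < 0.05 measures whether a global
    class/burden association leaks into spurious local correlations.
    Alterations are fully private here (``recurrent_share=0``): recurrent
    tier-shared segments consistently alter the same genes in high-burden
    classes, which is a local mechanism, not pure global coupling.
    Power: cohorts with ``n_planted`` genes coupled at ``target_r``; the
    fraction of planted genes flagged.
    """
    null_flagged = null_total = 0
    hit = planted_total = 0
    for i in range(n_seeds):
        cseed = int(stage_rng(seed, f"localscreen/{i}").integers(2**31))
        cfg = SimulationConfig(n_cpg=n_cpg, n_genes=n_genes, n_snp=n_snp,
                               recurrent_share=0.0, seed=cseed)
        cohort = simulate_cohort(cfg)
        res = _gene_screen(cohort, n_perm, stage_rng(seed, f"localscreen/null/{i}"))
        ok = res["q"].notna()
        null_flagged += int((res.loc[ok, "q"] < q_threshold).sum())
        null_total += int(ok.sum())

        cohort2 = simulate_cohort(cfg)
        genes = list(cohort2.cpg_annotation["gene"].dropna().unique()[:n_planted])
        plant_local_coupling(cohort2, genes, target_r=target_r,
                             seed=stage_rng(seed, f"localscreen/plant/{i}"))
        res2 = _gene_screen(cohort2, n_perm, stage_rng(seed, f"localscreen/alt/{i}"))
        flagged = set(res2.loc[res2["q"] < q_threshold, "unit"])
        hit += len(flagged & set(genes))
        planted_total += len(genes)
    return {
        "null_fpr": null_flagged / null_total,
        "power": hit / planted_total,
        "n_seeds": n_seeds,
        "n_null_units": null_total,
        "n_planted": planted_total,
    }


def rpmm_recovery(seed: int, n_seeds: int = 3) -> dict:
    """Adjusted Rand index of RPMM leaves vs planted 4-class labels.

    Well-separated 4-class cohorts: 40 samples, 200 CpGs, beta precision
    100 (nested class-mean grid spanning [0.15, 0.85]).
    """
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for i in range(n_seeds):
        cseed = int(stage_rng(seed, f"rpmmrec/{i}").integers(2**31))
        cfg = SimulationConfig(
            n_tumors=40, n_normals=2, n_cpg=200, n_genes=100, n_snp=300,
            n_classes=4, beta_precision=100.0, class_burden_targets=[0.05] * 4,
            seed=cseed,
        )
        cohort = simulate_cohort(cfg)
        classing = rpmm_fit(cohort.beta[list(cohort.tumors)].T, seed=cseed)
        truth = cohort.truth.class_labels
        aris.append(
            float(adjusted_rand_score(truth, classing.leaf_labels.loc[truth.index]))
        )
    return {"ari": aris, "ari_min": min(aris), "ari_mean": float(np.mean(aris))}


def hmm_recovery(seed: int, n_snp: int = 5000) -> dict:
    """State-recovery accuracy of the Viterbi caller at sd=0.2, p_stay=0.98."""
    cfg = SimulationConfig(n_cpg=40, n_genes=20, n_snp=n_snp, log_ratio_sd=0.2,
                           seed=seed)
    cohort = simulate_cohort(cfg)
    model = CNHmmModel(emission_sd=0.2, p_stay=0.98)
    states = call_state_matrix(cohort.log_ratios, cohort.snp_annotation, model)
    acc = float((states.to_numpy() == cohort.cn_states.to_numpy()).mean())
    return {"accuracy": acc, "n_loci": n_snp, "n_tumors": cfg.n_tumors}


def line1_analysis(seed: int, n_snp: int = 2000) -> dict:
    """High/low CNA grouping and LINE-1 difference on one default cohort.

    Clusters tumors on Hamming/Ward, dichotomizes by burden, and compares
    LINE-1 percent methylation between the groups.
    """
    cfg = SimulationConfig(n_cpg=200, n_genes=100, n_snp=n_snp, seed=seed)
    cohort = simulate_cohort(cfg)
    groups = dichotomize_cna(
        ward_cluster(hamming_matrix(cohort.cn_states)), burden(cohort.cn_states)
    )
    summary = line1_summary(cohort.line1)
    return line1_group_difference(summary, groups)


def line1_ci_coverage(
    seed: int,
    n_rep: int = 2000,
    mu_high: float = 52.0,
    mu_low: float = 65.2,
    sd: float = 8.0,
    n_high: int = 6,
    n_low: int = 5,
) -> dict:
    """Coverage of the Welch 95% CI for the LINE-1 group difference.

    Draws group samples around planted means and checks how often the
    interval covers the planted difference; nominal coverage is 95%.
    """
    rng = stage_rng(seed, "line1cov")
    truth = mu_high - mu_low
    covered = 0
    idx = [f"s{i}" for i in range(n_high + n_low)]
    grp = pd.Series(["high"] * n_high + ["low"] * n_low, index=idx)
    for _ in range(n_rep):
        vals = np.concatenate(
            [rng.normal(mu_high, sd, n_high), rng.normal(mu_low, sd, n_low)]
        )
        out = line1_group_difference(pd.Series(vals, index=idx), grp)
        covered += out["ci_low"] <= truth <= out["ci_high"]
    return {"coverage": covered / n_rep, "n_rep": n_rep, "true_difference": truth}
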