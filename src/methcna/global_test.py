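"""Global association between methylation classes and CNA burden.

The headline question — do tumors with similar methylation profiles carry
similar genome-wide copy-number burden? — is tested by a Kruskal-Wallis
statistic on per-tumor burden grouped by methylation class, with the null
distribution obtained by permuting class labels over tumors (10,000
permutations by default). The permutation p uses the add-one estimator
p = (1 + #{H_perm >= H_obs}) / (n_perm + 1), which never returns 0.

Clinical-covariate checks mirror the companion analysis: Fisher's exact
test for stage (I/II vs III/IV) and HPV16 status against the high/low CNA
grouping, a Monte-Carlo Fisher test for tumor site (more than two levels),
and a Wilcoxon rank-sum test for age.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "kruskal_wallis",
    "GlobalTestResult",
    "permutation_test_global",
    "fisher_exact_mc",
    "covariate_tests",
]


def kruskal_wallis(values, groups) -> float:
    """Kruskal-Wallis H with midrank ties correction.

    H = [12/(n(n+1)) * sum_g n_g (rbar_g - rbar)^2] / (1 - sum(t^3-t)/(n^3-n))
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be matching 1-D arrays")
    uniq, inv = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    n = values.size
    ranks = rankdata(values)
    sums = np.bincount(inv, weights=ranks)
    counts = np.bincount(inv)
    H = 12.0 / (n * (n + 1)) * np.sum(sums**2 / counts) - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # all values identical
        return 0.0
    return float(H / denom)


@dataclasses.dataclass
class GlobalTestResult:
    H: float
    p: float
    n_perm: int
    per_class: pd.DataFrame  # class, n, median/mean burden

    def to_frame(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out.insert(0, "H", self.H)
        out.insert(1, "p", self.p)
        out.insert(2, "n_perm", self.n_perm)
        return out


def _perm_H(values: np.ndarray, inv: np.ndarray, n_groups: int,
            n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """H for n_perm random relabelings, vectorized over permutations."""
    n = values.size
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:
        return np.zeros(n_perm)
    counts = np.bincount(inv, minlength=n_groups).astype(float)
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), inv] = 1.0
    # permuting labels == permuting the rank vector against fixed labels
    perm_ranks = np.empty((n_perm, n))
    for b in range(n_perm):
        perm_ranks[b] = ranks[rng.permutation(n)]
    sums = perm_ranks @ onehot  # (n_perm, n_groups)
    H = 12.0 / (n * (n + 1)) * np.sum(sums**2 / counts, axis=1) - 3.0 * (n + 1)
    return H / denom


def permutation_test_global(
    burden: pd.Series | np.ndarray,
    classes: pd.Series | np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> GlobalTestResult:
    """Permutation Kruskal-Wallis test of burden vs class membership.

    Class labels are permuted over tumors ``n_perm`` times;
    p = (1 + #{H_perm >= H_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    b = np.asarray(burden, dtype=float)
    g = np.asarray(classes)
    uniq, inv = np.unique(g, return_inverse=True)
    H_obs = kruskal_wallis(b, g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    H_perm = _perm_H(b, inv, uniq.size, n_perm, rng)
    p = (1.0 + np.sum(H_perm >= H_obs - 1e-12)) / (n_perm + 1.0)
    per_class = pd.DataFrame(
        {
            "class": uniq,
            "n": np.bincount(inv),
            "median_burden": [float(np.median(b[inv == k])) for k in range(uniq.size)],
            "mean_burden": [float(np.mean(b[inv == k])) for k in range(uniq.size)],
        }
    )
    return GlobalTestResult(H=float(H_obs), p=float(p), n_perm=n_perm,
                            per_class=per_class)


def fisher_exact_mc(
    table: np.ndarray, n_draws: int = 100000, seed: int | np.random.Generator = 0
) -> float:
    """Monte-Carlo Fisher exact p for an r x c contingency table.

    Samples tables with the observed margins and compares their
    probability (product multivariate hypergeometric) to the observed
    table's; p uses the add-one estimator.
    """
    table = np.asarray(table, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    def log_prob(tabs):
        from scipy.special import gammaln

        tabs = np.asarray(tabs, dtype=float)
        const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(table.sum() + 1)
        return const - gammaln(tabs + 1).sum(axis=(-2, -1))

    lp_obs = log_prob(table)
    sampled = stats.random_table(row, col).rvs(n_draws, random_state=rng)
    lp = log_prob(sampled)
    return float((1.0 + np.sum(lp <= lp_obs + 1e-9)) / (n_draws + 1.0))


def covariate_tests(
    group_labels: pd.Series,
    metadata: pd.DataFrame,
    n_draws: int = 100000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Association of the high/low CNA grouping with clinical covariates.

    ``metadata`` needs columns ``stage`` (I-IV), ``site``, ``hpv16``
    (bool/0-1), ``age``; indexed by tumor id. Rows with missing covariate
    values are dropped per test; tests with an empty stratum are skipped
    with a flag.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = metadata.loc[group_labels.index]
    grp = group_labels.astype(str)
    rows = []

    def add(covariate, test, p, note=""):
        rows.append({"covariate": covariate, "test": test, "p": p, "note": note})

    # stage dichotomized I/II vs III/IV
    stage = meta["stage"].map(
        lambda s: "I/II" if str(s) in {"I", "II"} else ("III/IV" if str(s) in {"III", "IV"} else np.nan)
    )
    tab = pd.crosstab(stage, grp)
    if tab.shape == (2, 2) and (tab.to_numpy().sum(axis=1) > 0).all():
        _, p = stats.fisher_exact(tab.to_numpy())
        add("stage", "fisher_exact", float(p))
    else:
        add("stage", "fisher_exact", np.nan, "skipped: empty stratum")

    hpv = meta["hpv16"].astype(float)
    tab = pd.crosstab(hpv, grp)
    if tab.shape == (2, 2):
        _, p = stats.fisher_exact(tab.to_numpy())
        add("hpv16", "fisher_exact", float(p))
    else:
        add("hpv16", "fisher_exact", np.nan, "skipped: empty stratum")

    tab = pd.crosstab(meta["site"], grp)
    if tab.shape[0] >= 2 and tab.shape[1] == 2:
        p = fisher_exact_mc(tab.to_numpy(), n_draws=n_draws, seed=rng)
        add("site", "fisher_monte_carlo", p)
    else:
        add("site", "fisher_monte_carlo", np.nan, "skipped: empty stratum")

    age = meta["age"].astype(float)
    sides = grp.unique()
    a0 = age[grp == sides[0]].dropna()
    a1 = age[grp == sides[1]].dropna() if len(sides) > 1 else pd.Series(dtype=float)
    if len(a0) and len(a1):
        res = stats.mannwhitneyu(a0, a1, alternative="two-sided")
        add("age", "wilcoxon_rank_sum", float(res.pvalue))
    else:
        add("age", "wilcoxon_rank_sum", np.nan, "skipped: empty stratum")

    return pd.DataFrame(rows)
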