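"""Ward clustering of copy-number and methylation profiles, CNA grouping,
and the LINE-1 global-methylation comparison.

Copy-number profiles are compared by Hamming distance (number of loci at
which the integer states differ; pairwise-complete, rescaled to the full
locus count) and clustered with Ward's minimum-variance method via the
Lance-Williams recurrence applied to squared input distances (the
"ward.D2" convention). Cutting the tumor dendrogram into two clusters and
labelling the cluster with the larger mean burden "high" gives the
high/low CNA grouping; LINE-1 percent methylation is then compared between
groups with a Welch-based difference and 95% confidence interval.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hamming_matrix",
    "Dendrogram",
    "ward_cluster",
    "cut_k",
    "dichotomize_cna",
    "line1_group_difference",
    "export_orderings",
]


def hamming_matrix(states: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hamming distances between tumors (columns of ``states``).

    Missing loci are skipped pairwise and the mismatch count rescaled to
    the full locus number; a pair with no co-observed loci is an error.
    """
    X = states.to_numpy(dtype=float).T  # tumors x loci
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 tumors")
    obs = ~np.isnan(X)
    D = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = (X[i][None, :] != X) & both
        n_both = both.sum(axis=1)
        if np.any(n_both == 0):
            j = int(np.flatnonzero(n_both == 0)[0])
            if j != i:
                raise ValueError(
                    f"tumors {states.columns[i]!r} and {states.columns[j]!r} share no observed loci"
                )
        with np.errstate(invalid="ignore"):
            D[i] = diff.sum(axis=1) * (m / n_both)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=states.columns, columns=states.columns)


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge sequence in scipy convention.

    Leaves are 0..n-1; the i-th merge creates cluster n+i. ``merges`` has
    rows (id_a, id_b, height, size).
    """

    merges: np.ndarray  # (n-1, 4)
    labels: pd.Index
    metric: str
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list:
        """Left-to-right leaf order of the tree."""
        n = self.n_leaves

        def walk(node):
            if node < n:
                return [node]
            a, b = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            return walk(a) + walk(b)

        return [self.labels[i] for i in walk(2 * n - 2)] if n > 1 else list(self.labels)

    def to_newick(self) -> str:
        n = self.n_leaves

        def walk(node):
            if node < n:
                return str(self.labels[node])
            a, b = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            h = self.merges[node - n, 2]
            return f"({walk(a)},{walk(b)}):{h:.6g}"

        return walk(2 * n - 2) + ";" if n > 1 else f"({self.labels[0]});"


def ward_cluster(
    dist: pd.DataFrame | np.ndarray, squared_update: bool = True,
    metric: str = "hamming",
) -> Dendrogram:
    """Ward agglomeration of a precomputed distance matrix.

    Applies the Lance-Williams Ward update to squared input distances and
    reports merge heights on the original scale ("ward.D2"; set
    ``squared_update=False`` for the raw-distance "ward.D" variant).
    Ties are broken toward the smallest pair of cluster indices.
    """
    if isinstance(dist, pd.DataFrame):
        labels = dist.index
        D = dist.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(dist, dtype=float).copy()
        labels = pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    W = D**2 if squared_update else D.copy()
    np.fill_diagonal(W, np.inf)
    size = {i: 1 for i in range(n)}
    cluster_id = list(range(n))  # active row -> cluster id
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    Wd = W.copy()
    for step in range(n - 1):
        sub = Wd[np.ix_(active, active)]
        np.fill_diagonal(sub, np.inf)
        flat = np.argmin(sub)
        ai, aj = divmod(flat, len(active))
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        ci, cj = cluster_id[i], cluster_id[j]
        h = np.sqrt(Wd[i, j]) if squared_update else Wd[i, j]
        ni, nj = size[ci], size[cj]  # sizes stay tied to rows i and j
        merges[step] = (min(ci, cj), max(ci, cj), h, ni + nj)
        # Lance-Williams Ward update against every other active cluster
        for a in active:
            if a in (i, j):
                continue
            nk = size[cluster_id[a]]
            Wd[i, a] = Wd[a, i] = (
                (ni + nk) * Wd[i, a] + (nj + nk) * Wd[j, a] - nk * Wd[i, j]
            ) / (ni + nj + nk)
        new_id = n + step
        size[new_id] = ni + nj
        cluster_id[i] = new_id
        active.remove(j)
    return Dendrogram(merges=merges, labels=labels, metric=metric,
                      linkage="ward.D2" if squared_update else "ward.D")


def cut_k(dend: Dendrogram, k: int) -> pd.Series:
    """Cluster labels (1..k) from cutting the dendrogram into k clusters."""
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValueError("k out of range")
    parent = {}
    for step in range(n - 1 - (k - 1)):
        a, b = int(dend.merges[step, 0]), int(dend.merges[step, 1])
        parent[a] = n + step
        parent[b] = n + step

    def find(x):
        while x in parent:
            x = parent[x]
        return x

    roots = {}
    labels = np.zeros(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return pd.Series(labels, index=dend.labels, name="cluster")


def dichotomize_cna(dend: Dendrogram, burden: pd.Series) -> pd.Series:
    """High/low CNA group labels from a 2-cut of the tumor dendrogram.

    The cluster with the larger mean burden is "high"; on an exact tie
    the larger cluster is labelled "low" with a warning.
    """
    clusters = cut_k(dend, 2)
    means = burden.groupby(clusters).mean()
    if len(means) == 1:
        return pd.Series("low", index=clusters.index, name="cna_group")
    if means.iloc[0] == means.iloc[1]:
        import warnings

        warnings.warn("equal mean burden between clusters; larger cluster -> low")
        sizes = clusters.value_counts()
        low_cluster = sizes.idxmax()
    else:
        low_cluster = means.idxmin()
    labels = clusters.map(lambda c: "low" if c == low_cluster else "high")
    labels.name = "cna_group"
    return labels


def line1_group_difference(
    line1: pd.Series, groups: pd.Series, conf: float = 0.95
) -> dict:
    """Difference in mean LINE-1 percent methylation, high minus low.

    Returns dict with ``difference`` (percentage points), ``ci_low``,
    ``ci_high`` (Welch two-sided interval) and group summaries. If a
    group has fewer than 2 values the CI is flagged unavailable.
    """
    common = line1.index.intersection(groups.index)
    x = line1.loc[common]
    g = groups.loc[common]
    hi = x[g == "high"].dropna().to_numpy(dtype=float)
    lo = x[g == "low"].dropna().to_numpy(dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups need at least one LINE-1 value")
    diff = float(hi.mean() - lo.mean())
    out = {
        "difference": diff,
        "n_high": int(hi.size),
        "n_low": int(lo.size),
        "mean_high": float(hi.mean()),
        "mean_low": float(lo.mean()),
        "ci_low": np.nan,
        "ci_high": np.nan,
        "ci_available": False,
    }
    if hi.size >= 2 and lo.size >= 2:
        vh, vl = hi.var(ddof=1), lo.var(ddof=1)
        se = np.sqrt(vh / hi.size + vl / lo.size)
        if se > 0:
            df = (vh / hi.size + vl / lo.size) ** 2 / (
                (vh / hi.size) ** 2 / (hi.size - 1)
                + (vl / lo.size) ** 2 / (lo.size - 1)
            )
            tcrit = stats.t.ppf(0.5 + conf / 2.0, df)
            out.update(
                ci_low=float(diff - tcrit * se),
                ci_high=float(diff + tcrit * se),
                ci_available=True,
                df=float(df),
            )
        else:
            out.update(ci_low=diff, ci_high=diff, ci_available=True, df=np.nan)
    return out


def export_orderings(
    classing_frame: pd.DataFrame,
    beta: pd.DataFrame,
    cn_dend: Dendrogram,
) -> dict[str, list]:
    """Sample orderings used by the heatmap displays.

    Methylation: tumors ordered by RPMM leaf class, then by Ward/Euclidean
    leaf order within each class. Copy number: the CN dendrogram's leaf
    order.
    """
    meth_order: list = []
    for cls in sorted(classing_frame["leaf_class"].unique()):
        members = classing_frame.index[classing_frame["leaf_class"] == cls]
        if len(members) == 1:
            meth_order.extend(members)
            continue
        sub = beta.loc[:, members].T.to_numpy(dtype=float)
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        dend = ward_cluster(pd.DataFrame(d, index=members, columns=members),
                            metric="euclidean")
        meth_order.extend(dend.leaf_order())
    return {"methylation": meth_order, "copy_number": cn_dend.leaf_order()}
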