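"""Per-gene alteration tests: methylation (tumor vs normal) and copy number.

Methylation alteration at a unit is tested with a two-sided Welch
(unequal-variance) two-sample t-test of tumor beta against normal-tissue
beta; the reported mean alteration is mean(tumor) - mean(normal). Copy
number is tested with a one-sample t-test of the gene-averaged state
against the diploid expectation 2. Multiple testing is corrected with
q-values within one family per (alteration type x stratum), and the
volcano tables additionally stratify tumors by the left/right root split
of the methylation classing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .local import qvalues

__all__ = ["methylation_alteration", "cn_alteration", "stratified_volcano"]


def _finish(df: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = qvalues(df.loc[ok, "p"].to_numpy())
    df["q"] = q
    df["significant"] = df["q"] < q_threshold
    df["neg_log10_p"] = -np.log10(df["p"])
    return df


def methylation_alteration(
    tumor_beta: pd.DataFrame,
    normal_beta: pd.DataFrame,
    stratum: str = "all",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of tumor vs normal methylation per unit (gene or locus).

    Both inputs are units x samples with identical unit index. Units with
    fewer than 2 observed tumors or normals are excluded with a flag;
    zero variance in both groups gives t=0, p=1 when the means agree and
    a degenerate-exclusion flag when they do not.
    """
    units = tumor_beta.index
    T = tumor_beta.to_numpy(dtype=float)
    N = normal_beta.loc[units].to_numpy(dtype=float)
    rows = []
    for i, unit in enumerate(units):
        t_vals = T[i][~np.isnan(T[i])]
        n_vals = N[i][~np.isnan(N[i])]
        if t_vals.size < 2 or n_vals.size < 2:
            rows.append((unit, np.nan, np.nan, np.nan, "fewer than 2 per group"))
            continue
        delta = float(t_vals.mean() - n_vals.mean())
        if t_vals.var(ddof=1) == 0 and n_vals.var(ddof=1) == 0:
            if delta == 0:
                rows.append((unit, 0.0, 0.0, 1.0, ""))
            else:
                rows.append((unit, delta, np.nan, np.nan, "degenerate: zero variance"))
            continue
        t, p = stats.ttest_ind(t_vals, n_vals, equal_var=False)
        rows.append((unit, delta, float(t), float(p), ""))
    df = pd.DataFrame(rows, columns=["unit", "mean_alteration", "t", "p", "flag"])
    df.insert(1, "type", "methylation")
    df.insert(2, "stratum", stratum)
    return _finish(df, q_threshold)


def cn_alteration(
    cn_gene_matrix: pd.DataFrame,
    stratum: str = "all",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sample t-test of gene-averaged copy number against 2 per unit."""
    units = cn_gene_matrix.index
    X = cn_gene_matrix.to_numpy(dtype=float)
    rows = []
    for i, unit in enumerate(units):
        vals = X[i][~np.isnan(X[i])]
        if vals.size < 2:
            rows.append((unit, np.nan, np.nan, np.nan, "fewer than 2 tumors"))
            continue
        delta = float(vals.mean() - 2.0)
        if vals.var(ddof=1) == 0:
            if delta == 0:
                rows.append((unit, 0.0, 0.0, 1.0, ""))
            else:
                rows.append((unit, delta, np.nan, np.nan, "degenerate: zero variance"))
            continue
        t, p = stats.ttest_1samp(vals, 2.0)
        rows.append((unit, delta, float(t), float(p), ""))
    df = pd.DataFrame(rows, columns=["unit", "mean_alteration", "t", "p", "flag"])
    df.insert(1, "type", "copy_number")
    df.insert(2, "stratum", stratum)
    return _finish(df, q_threshold)


def stratified_volcano(
    gene_beta_tumor: pd.DataFrame,
    gene_beta_normal: pd.DataFrame,
    gene_cn: pd.DataFrame,
    root_side: pd.Series,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Alteration tables for strata {all, left, right}.

    ``root_side`` maps tumor ids to "left"/"right". Strata with fewer
    than 2 tumors are skipped. Normals are shared across strata for the
    methylation comparison. Returns one long volcano table.
    """
    tumors = gene_beta_tumor.columns
    strata: dict[str, pd.Index] = {"all": tumors}
    for side in ("left", "right"):
        members = root_side.index[root_side == side]
        strata[side] = tumors.intersection(members)
    tables = []
    for name, members in strata.items():
        if len(members) < 2:
            continue  # skipped stratum
        tables.append(
            methylation_alteration(
                gene_beta_tumor[members], gene_beta_normal, stratum=name,
                q_threshold=q_threshold,
            )
        )
        tables.append(
            cn_alteration(gene_cn[gene_cn.columns.intersection(members)],
                          stratum=name, q_threshold=q_threshold)
        )
    return pd.concat(tables, ignore_index=True)
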