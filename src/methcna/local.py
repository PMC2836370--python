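"""Locus- and gene-level methylation vs copy-number correlation screen.

Each CpG is matched to the nearest SNP on the same chromosome (ties to the
lower coordinate). Per matched pair — or per gene after promoter/gene
averaging — the tumor-level Pearson correlation between methylation and
copy-number state is computed, with a two-sided permutation p-value
obtained by permuting the methylation vector's sample order (5,000
permutations by default, one shared permutation schedule across units so a
run is seed-stable). Multiple testing is controlled with Storey q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "match_loci",
    "gene_aggregate",
    "correlation_screen",
    "qvalues",
    "flag_significant",
]


def match_loci(
    cpg_annot: pd.DataFrame,
    snp_annot: pd.DataFrame,
    max_distance: float = np.inf,
) -> pd.DataFrame:
    """Match every CpG to its nearest same-chromosome SNP.

    Returns a table (cpg, snp, chrom, distance); CpGs farther than
    ``max_distance`` from any SNP, or on a chromosome with no SNPs, are
    reported with ``snp`` = NA and a reason flag instead of a match.
    Ties are broken toward the lower SNP coordinate.
    """
    out = []
    snp_by_chrom = {
        c: g.sort_values("start", kind="mergesort") for c, g in snp_annot.groupby("chrom")
    }
    for _, row in cpg_annot.iterrows():
        chrom, pos, cpg = row["chrom"], int(row["start"]), row["locus"]
        snps = snp_by_chrom.get(chrom)
        if snps is None or len(snps) == 0:
            out.append((cpg, pd.NA, chrom, np.nan, "no SNP on chromosome"))
            continue
        coords = snps["start"].to_numpy()
        d = np.abs(coords - pos)
        best = np.min(d)
        # ties -> lower coordinate: first index among sorted coords with d==best
        idx = int(np.flatnonzero(d == best)[0])
        if best > max_distance:
            out.append((cpg, pd.NA, chrom, float(best), "beyond max_distance"))
            continue
        out.append((cpg, snps["locus"].iloc[idx], chrom, float(best), ""))
    return pd.DataFrame(out, columns=["cpg", "snp", "chrom", "distance", "flag"])


def gene_aggregate(
    beta: pd.DataFrame,
    cn: pd.DataFrame,
    cpg_annot: pd.DataFrame,
    snp_annot: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter-averaged methylation and gene-averaged copy number.

    Gene methylation is the mean beta over the gene's upstream-of-TSS
    (promoter) CpGs; genes with no promoter CpG are excluded. Gene copy
    number is the mean state over all SNPs annotated to the gene; genes
    with no SNPs are excluded. Both returned as genes x samples frames.
    """
    cpg = cpg_annot.dropna(subset=["gene"])
    promoter = cpg[cpg["upstream"] == 1]
    promoter = promoter[promoter["locus"].isin(beta.index)]
    gene_beta = (
        beta.loc[promoter["locus"]]
        .groupby(promoter.set_index("locus")["gene"])
        .mean()
    )
    snp = snp_annot.dropna(subset=["gene"])
    snp = snp[snp["locus"].isin(cn.index)]
    gene_cn = cn.loc[snp["locus"]].groupby(snp.set_index("locus")["gene"]).mean()
    return gene_beta, gene_cn


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between paired (units x samples) matrices."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.sum(Xc * Yc, axis=1)
    den = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(Yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlation_screen(
    x_matrix: pd.DataFrame,
    y_matrix: pd.DataFrame,
    units: pd.DataFrame | None = None,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    level: str = "locus",
) -> pd.DataFrame:
    """Per-unit Pearson correlation with permutation p-values and q-values.

    ``x_matrix`` (methylation) and ``y_matrix`` (copy number) are units x
    samples. ``units`` optionally maps rows of x to rows of y (columns
    ``x``/``y``; default: identical row labels). The methylation vector is
    permuted; the copy-number vector stays fixed; one permutation schedule
    is shared by all units. Units with zero variance in either vector, or
    fewer than 3 complete pairs, are excluded with a flag.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if units is None:
        common = x_matrix.index.intersection(y_matrix.index)
        units = pd.DataFrame({"x": common, "y": common, "unit": common})
    else:
        units = units.rename(columns={}).copy()
        if "unit" not in units.columns:
            units["unit"] = units["x"]
    samples = x_matrix.columns.intersection(y_matrix.columns)
    X = x_matrix.loc[units["x"], samples].to_numpy(dtype=float)
    Y = y_matrix.loc[units["y"], samples].to_numpy(dtype=float)
    n = len(samples)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    complete = ~(np.isnan(X) | np.isnan(Y))
    r_all = np.full(len(units), np.nan)
    flags = np.full(len(units), "", dtype=object)
    p_all = np.full(len(units), np.nan)
    for i in range(len(units)):
        m = complete[i]
        k = int(m.sum())
        if k < 3:
            flags[i] = "fewer than 3 complete pairs"
            continue
        x, y = X[i, m], Y[i, m]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            flags[i] = "zero variance"
            continue
        r = _pearson_rows(x[None, :], y[None, :])[0]
        r_all[i] = r
        if k == n:
            xp = x[perms]  # (n_perm, n)
        else:
            xp = x[_restricted_perms(perms, m)]
        rp = _pearson_rows(xp, np.broadcast_to(y, xp.shape))
        p_all[i] = (1.0 + np.sum(np.abs(rp) >= np.abs(r) - 1e-12)) / (n_perm + 1.0)

    out = pd.DataFrame(
        {
            "unit": units["unit"].to_numpy(),
            "level": level,
            "r": r_all,
            "p": p_all,
            "n": complete.sum(axis=1),
            "flag": flags,
        }
    )
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.sum() >= 1:
        q[ok.to_numpy()] = qvalues(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out[["unit", "level", "r", "p", "q", "n", "flag"]]


def _restricted_perms(perms: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Project a shared permutation schedule onto the observed subset.

    Keeps the relative order that each full-length permutation induces on
    the observed positions, so incomplete units reuse the shared schedule.
    """
    obs = np.flatnonzero(mask)
    pos = {s: i for i, s in enumerate(obs)}
    k = obs.size
    out = np.empty((perms.shape[0], k), dtype=int)
    for b in range(perms.shape[0]):
        seq = [pos[s] for s in perms[b] if s in pos]
        out[b] = seq
    return out


def qvalues(pvals: np.ndarray) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.95 as
    #{p > lambda}/(m (1-lambda)), a cubic polynomial is fit to the grid
    and evaluated at lambda -> 1, and the estimate is clamped to (0, 1].
    With fewer than 10 p-values pi0 falls back to 1, which reduces the
    q-values to Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 10:
        import warnings

        warnings.warn("fewer than 10 p-values; using pi0 = 1 (BH)")
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, 1.0))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def flag_significant(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Units passing q < threshold, sorted by p (ties by |r| descending)."""
    hits = results[results["q"] < q_threshold].copy()
    if hits.empty:
        return hits
    hits["_absr"] = -hits["r"].abs()
    hits = hits.sort_values(["p", "_absr"], kind="mergesort").drop(columns="_absr")
    return hits.reset_index(drop=True)
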