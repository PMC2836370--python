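"""Methylation beta values from two-color signals, and LINE-1 summaries.

The beta value at a CpG is computed from the methylated (M) and
unmethylated (U) fluorescence intensities as

    beta = max(M, 0) / (|U| + |M| + 100)

The +100 offset regularizes low-intensity probes, and the clamp/absolute
values make the estimate robust to background-subtracted negative signals;
the result always lies in [0, 1).

LINE-1 pyrosequencing reports percent methylation at four CpGs of the
LINE-1 consensus per reaction; a sample's global-methylation surrogate is
the mean over the four CpGs within each replicate, then the mean over
replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_beta", "beta_from_signal_table", "line1_summary"]


def compute_beta(M, U):
    """Methylation fraction beta = max(M,0) / (|U| + |M| + 100).

    Accepts scalars or arrays; inputs must be finite. Negative M is
    clamped to zero in the numerator but still contributes |M| to the
    denominator.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("signal intensities must be finite")
    beta = np.maximum(M, 0.0) / (np.abs(U) + np.abs(M) + 100.0)
    return beta if beta.ndim else float(beta)


def beta_from_signal_table(signals: pd.DataFrame) -> pd.DataFrame:
    """Convert a long signal-pair table to a loci x samples beta matrix.

    Expects columns ``locus``, ``sample``, ``M``, ``U``; one row per
    (locus, sample).
    """
    required = {"locus", "sample", "M", "U"}
    missing = required - set(signals.columns)
    if missing:
        raise ValueError(f"signal table missing columns: {sorted(missing)}")
    beta = compute_beta(signals["M"].to_numpy(), signals["U"].to_numpy())
    long = signals[["locus", "sample"]].copy()
    long["beta"] = beta
    wide = long.pivot(index="locus", columns="sample", values="beta")
    wide = wide.loc[pd.unique(signals["locus"]), pd.unique(signals["sample"])]
    wide.index.name = None
    wide.columns.name = None
    return wide


def line1_summary(records: pd.DataFrame) -> pd.Series:
    """Per-sample mean LINE-1 percent methylation.

    Parameters
    ----------
    records
        Long table with columns ``sample``, ``replicate`` and four CpG
        columns ``cpg1..cpg4`` (percent methylation in [0,100]); one row
        per pyrosequencing replicate.

    Returns
    -------
    Series indexed by sample: mean over the 4 CpGs within each replicate,
    then mean over replicates.
    """
    cpg_cols = [c for c in records.columns if c.startswith("cpg")]
    if len(cpg_cols) != 4:
        raise ValueError(f"expected exactly 4 CpG columns, found {cpg_cols}")
    vals = records[cpg_cols]
    if vals.isna().any().any():
        bad = records.loc[vals.isna().any(axis=1), "sample"].iloc[0]
        raise ValueError(f"replicate for sample {bad!r} has missing CpG values")
    per_replicate = vals.mean(axis=1)
    out = per_replicate.groupby(records["sample"], sort=True).mean()
    out.name = "line1_pct"
    return out
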