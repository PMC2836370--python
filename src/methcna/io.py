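"""TSV matrix and annotation I/O with validation.

Matrices are stored loci-in-rows on disk (first column = locus id, header =
sample ids) and handled in memory as pandas DataFrames indexed the same
way. Missing values are written as ``NA`` and kept as NaN; they are never
imputed. Annotations use a BED-like TSV (0-based start coordinates).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
]

MATRIX_KINDS = ("beta", "cn_state", "log_ratio", "signal_pair")

#: float format used everywhere so identical runs are byte-identical on disk
FLOAT_FORMAT = "%.10g"


class MatrixValidationError(ValueError):
    """A matrix or annotation failed a format/domain check."""


def _check_unique(ids: Iterable[str], what: str, path) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicated {what} ids in {path}: {dup[:5]}")


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a loci x samples TSV matrix and validate entries for *kind*.

    Parameters
    ----------
    path
        TSV file; first column = locus id, header row = sample ids.
    kind
        One of ``beta`` (entries in [0,1]), ``cn_state`` (non-negative
        integers), ``log_ratio`` or ``signal_pair`` (any finite real).
        ``NA`` cells are preserved as NaN.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {MATRIX_KINDS}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    _check_unique(df.index, "locus", path)
    _check_unique(df.columns, "sample", path)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise MatrixValidationError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            ) from None
    values = df.to_numpy(dtype=float)
    finite = np.isfinite(values)
    if kind == "beta":
        bad = finite & ((values < 0.0) | (values > 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixValidationError(
                f"beta value {values[i, j]} outside [0,1] at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
    elif kind == "cn_state":
        bad = finite & ((values < 0.0) | (values != np.round(values)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixValidationError(
                f"copy-number state {values[i, j]} is not a non-negative integer at "
                f"row {df.index[i]!r}, column {df.columns[j]!r}"
            )
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix TSV (``NA`` for missing, stable float formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT)


ANNOTATION_COLUMNS = ["chrom", "start", "locus", "gene", "upstream"]


def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like locus annotation TSV.

    Columns: chrom, start (0-based), locus id, gene id (empty allowed),
    upstream-of-TSS flag (``1``/``0``; empty for SNP loci). Output is
    sorted by (chrom, start) with the original locus ids preserved.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        names=ANNOTATION_COLUMNS,
        dtype={"chrom": str, "locus": str, "gene": str},
        na_values=["NA", ""],
        keep_default_na=False,
    )
    if (df["start"] < 0).any():
        bad = df.loc[df["start"] < 0, "locus"].iloc[0]
        raise MatrixValidationError(f"negative coordinate for locus {bad!r} in {path}")
    _check_unique(df["locus"], "locus", path)
    flags = df["upstream"].dropna()
    if not flags.isin([0, 1, "0", "1", 0.0, 1.0]).all():
        bad = flags[~flags.isin([0, 1, "0", "1", 0.0, 1.0])].iloc[0]
        raise MatrixValidationError(f"unknown upstream flag value {bad!r} in {path}")
    df["upstream"] = pd.to_numeric(df["upstream"], errors="coerce")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[ANNOTATION_COLUMNS].copy()
    out["upstream"] = out["upstream"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, sep="\t", index=False, na_rep="")


@dataclasses.dataclass
class AnalysisConfig:
    """Parameters for the end-to-end pipeline.

    Defaults follow the analysis conventions: 5,000 permutations for the
    local correlation screen, 10,000 for the global class/burden test, and
    a q<0.05 significance rule.
    """

    seed: int = 0
    n_perm_local: int = 5000
    n_perm_global: int = 10000
    q_threshold: float = 0.05
    match_max_distance: float = float("inf")
    hmm_emission_sd: float = 0.2
    hmm_stay_prob: float = 0.98
    rpmm_max_depth: int = 3
    rpmm_min_node_weight: float = 2.0
    rpmm_em_tol: float = 1e-6
    # input paths (optional; pipeline may receive in-memory tables instead)
    beta_path: str | None = None
    cn_path: str | None = None
    log_ratio_path: str | None = None
    cpg_annotation_path: str | None = None
    snp_annotation_path: str | None = None
    metadata_path: str | None = None
    line1_path: str | None = None

    def validate(self) -> "AnalysisConfig":
        if self.n_perm_local < 1 or self.n_perm_global < 1:
            raise ValueError("permutation counts must be >= 1")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must be in (0,1)")
        if self.hmm_emission_sd <= 0:
            raise ValueError("hmm_emission_sd must be positive")
        if not (0.0 < self.hmm_stay_prob < 1.0):
            raise ValueError("hmm_stay_prob must be in (0,1)")
        if self.rpmm_max_depth < 1 or self.rpmm_min_node_weight <= 0:
            raise ValueError("invalid rpmm parameters")
        return self

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        import json

        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
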