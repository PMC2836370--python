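"""Five-state Gaussian copy-number HMM and the per-tumor burden statistic.

States are integer copy numbers {0,1,2,3,4}. A locus with state s emits a
log2 tumor/normal ratio distributed N(log2(max(s, 0.5)/2), sd); the 0.5
floor keeps the homozygous-deletion mean finite. Transitions stay in the
current state with probability ``p_stay`` and split the remainder
uniformly over the other four states. Chromosomes are decoded
independently by Viterbi.

Genome-wide allelic-imbalance burden for a tumor is the mean of |CNS - 2|
over loci, 0 for a fully diploid genome and at most 2 for states in 0..4.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["CNHmmModel", "viterbi_states", "call_state_matrix", "burden"]

STATES = np.arange(5)

# tie-break preference: closest to diploid, then lower state
_TIE_ORDER = np.array([2, 1, 3, 0, 4])


@dataclasses.dataclass
class CNHmmModel:
    """Emission/transition parameters of the 5-state copy-number HMM."""

    emission_sd: float = 0.2
    p_stay: float = 0.98
    initial: np.ndarray | None = None  # default: uniform over 5 states

    def __post_init__(self):
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")
        if not (0.0 < self.p_stay < 1.0):
            raise ValueError("p_stay must be in (0,1)")
        if self.initial is None:
            self.initial = np.full(5, 0.2)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (5,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must be length 5 and sum to 1")

    @property
    def emission_means(self) -> np.ndarray:
        return np.log2(np.maximum(STATES, 0.5) / 2.0)

    @property
    def log_transition(self) -> np.ndarray:
        T = np.full((5, 5), (1.0 - self.p_stay) / 4.0)
        np.fill_diagonal(T, self.p_stay)
        return np.log(T)


def _emission_loglik(ratios: np.ndarray, model: CNHmmModel) -> np.ndarray:
    """(n_loci, 5) Gaussian log density of each ratio under each state."""
    mu = model.emission_means
    sd = model.emission_sd
    z = (ratios[:, None] - mu[None, :]) / sd
    return -0.5 * z**2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def _argmax_tiebreak(scores: np.ndarray) -> np.ndarray:
    """Argmax over the last axis, ties resolved toward diploid then lower.

    Relies on np.argmax returning the first maximum: columns are scanned
    in preference order 2,1,3,0,4 and the winner mapped back.
    """
    reordered = scores[..., _TIE_ORDER]
    return _TIE_ORDER[np.argmax(reordered, axis=-1)]


def viterbi_states(log_ratios: np.ndarray, model: CNHmmModel) -> np.ndarray:
    """Maximum-a-posteriori state path for one chromosome's ratio track.

    Ties in the dynamic program are broken toward the state closer to 2,
    then the lower state.
    """
    x = np.asarray(log_ratios, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("log_ratios must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("log_ratios contain non-finite values")
    logB = _emission_loglik(x, model)
    logT = model.log_transition
    n = x.size
    delta = np.log(model.initial) + logB[0]
    back = np.zeros((n, 5), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + logT  # (from, to)
        back[t] = _argmax_tiebreak(cand.T)
        delta = cand[back[t], np.arange(5)] + logB[t]
    path = np.zeros(n, dtype=int)
    path[-1] = _argmax_tiebreak(delta)
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def path_logprob(path: np.ndarray, log_ratios: np.ndarray, model: CNHmmModel) -> float:
    """Joint log probability of a state path and the observed ratios."""
    x = np.asarray(log_ratios, dtype=float)
    path = np.asarray(path, dtype=int)
    logB = _emission_loglik(x, model)
    logT = model.log_transition
    lp = np.log(model.initial[path[0]]) + logB[0, path[0]]
    lp += logT[path[:-1], path[1:]].sum()
    lp += logB[np.arange(1, x.size), path[1:]].sum()
    return float(lp)


def call_state_matrix(
    log_ratios: pd.DataFrame, snp_annotation: pd.DataFrame, model: CNHmmModel
) -> pd.DataFrame:
    """Viterbi-decode every tumor, chromosome by chromosome.

    ``log_ratios`` is loci x tumors; ``snp_annotation`` maps each locus to
    a chromosome. Chromosomes with no loci are skipped. Returns an integer
    state matrix with the same shape/labels as the input.
    """
    chrom = snp_annotation.set_index("locus").loc[log_ratios.index, "chrom"]
    states = pd.DataFrame(
        2, index=log_ratios.index, columns=log_ratios.columns, dtype=int
    )
    for c in pd.unique(chrom):
        idx = chrom.index[chrom == c]
        block = log_ratios.loc[idx]
        for tumor in block.columns:
            states.loc[idx, tumor] = viterbi_states(block[tumor].to_numpy(), model)
    return states


def burden(states: pd.DataFrame | np.ndarray) -> pd.Series:
    """Per-tumor mean |CNS - 2| over loci (allelic-imbalance burden).

    Missing loci are excluded pairwise; a tumor with no observed loci is
    an error.
    """
    if isinstance(states, pd.DataFrame):
        vals = states.to_numpy(dtype=float)
        tumors = states.columns
    else:
        vals = np.asarray(states, dtype=float)
        tumors = pd.RangeIndex(vals.shape[1])
    dev = np.abs(vals - 2.0)
    n_obs = np.sum(~np.isnan(dev), axis=0)
    if np.any(n_obs == 0):
        bad = tumors[np.asarray(n_obs == 0)][0]
        raise ValueError(f"tumor {bad!r} has no observed copy-number states")
    out = pd.Series(np.nanmean(dev, axis=0), index=tumors, name="burden")
    return out
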