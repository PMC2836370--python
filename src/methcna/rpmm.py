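"""Recursively partitioned beta-mixture clustering of methylation profiles.

Samples are described by beta values at p CpGs. A node of the tree models
its samples as a 2-component mixture in which each component k has
independent Beta(a_jk, b_jk) emissions per CpG j. Fitting is weighted EM:
each sample enters a node with a soft membership weight inherited from its
parent responsibilities, and the node's EM maximizes the weight-adjusted
observed-data log-likelihood. A split is kept when the 2-component BIC
beats the 1-component BIC at that node and both children retain enough
effective weight; otherwise the node is a leaf (a methylation class).
Leaves are numbered left to right, with "left" canonically the child whose
samples are less methylated on average, and the two subtrees of the root
define the left/right class grouping used by the stratified analyses.

Numerics: beta values are clamped to [1e-6, 1-1e-6] (the beta
log-likelihood diverges at 0 and 1); weighted beta MLEs solve the digamma
score equations by damped Newton steps from a method-of-moments start,
falling back to moments if Newton leaves the feasible box [1e-4, 1e4].
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, logsumexp, polygamma

from ._rng import stage_rng

__all__ = [
    "BetaMixtureNode",
    "RPMMClassing",
    "fit_beta_mixture",
    "weighted_beta_mle",
    "rpmm_fit",
    "root_grouping",
]

CLAMP = 1e-6
PARAM_LO, PARAM_HI = 1e-4, 1e4


def _clamp(X: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(X, dtype=float), CLAMP, 1.0 - CLAMP)


def weighted_beta_mle(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column weighted MLE of beta parameters.

    Parameters
    ----------
    x : (n, p) clamped beta values
    w : (n,) non-negative sample weights with positive sum

    Returns (a, b), each shape (p,), clipped to [1e-4, 1e4].
    """
    W = w.sum()
    if W <= 0:
        raise ValueError("total weight must be positive")
    x = _clamp(x)
    mean = w @ x / W
    var = w @ (x - mean) ** 2 / W
    var = np.maximum(var, 1e-10)
    # method of moments
    phi = np.clip(mean * (1 - mean) / var - 1.0, 1e-2, PARAM_HI)
    a = np.clip(mean * phi, PARAM_LO, PARAM_HI)
    b = np.clip((1 - mean) * phi, PARAM_LO, PARAM_HI)
    a_mom, b_mom = a.copy(), b.copy()

    pbar = w @ np.log(x) / W
    qbar = w @ np.log1p(-x) / W
    ok = np.ones_like(a, dtype=bool)
    for _ in range(60):
        f1 = digamma(a) - digamma(a + b) - pbar
        f2 = digamma(b) - digamma(a + b) - qbar
        if np.all(np.abs(f1) < 1e-10) and np.all(np.abs(f2) < 1e-10):
            break
        tri_ab = polygamma(1, a + b)
        j11 = polygamma(1, a) - tri_ab
        j22 = polygamma(1, b) - tri_ab
        det = j11 * j22 - tri_ab**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (j22 * f1 + tri_ab * f2) / det
        db = (tri_ab * f1 + j11 * f2) / det
        # damped multiplicative-safe step: a_new in [0.1a, 10a], always positive
        a_new = np.clip(a - np.clip(da, -9 * a, 0.9 * a), PARAM_LO, PARAM_HI)
        b_new = np.clip(b - np.clip(db, -9 * b, 0.9 * b), PARAM_LO, PARAM_HI)
        bad = ~(np.isfinite(a_new) & np.isfinite(b_new))
        ok &= ~bad
        a = np.where(bad, a, a_new)
        b = np.where(bad, b, b_new)
    ok &= np.isfinite(a) & np.isfinite(b)
    a = np.where(ok, np.clip(a, PARAM_LO, PARAM_HI), a_mom)
    b = np.where(ok, np.clip(b, PARAM_LO, PARAM_HI), b_mom)
    return a, b


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x, kind="mergesort")
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def _beta_loglik_rows(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n,) per-sample log-likelihood under per-CpG Beta(a_j, b_j)."""
    return np.log(x) @ (a - 1.0) + np.log1p(-x) @ (b - 1.0) - betaln(a, b).sum()


@dataclasses.dataclass
class BetaMixtureNode:
    """One node of the RPMM tree."""

    name: str
    sample_weight: np.ndarray  # (n,) prior membership weight of every sample
    a: np.ndarray | None = None  # (K, p) beta parameters of the children fit
    b: np.ndarray | None = None
    mix: np.ndarray | None = None  # (K,) mixing weights
    resp: np.ndarray | None = None  # (n, K) responsibilities
    loglik: float = np.nan
    bic1: float = np.nan
    bic2: float = np.nan
    split_accepted: bool = False
    children: Optional[list["BetaMixtureNode"]] = None
    leaf_index: int | None = None  # 1-based, set on leaves after fitting

    @property
    def effective_weight(self) -> float:
        return float(self.sample_weight.sum())

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "effective_weight": self.effective_weight,
            "split_accepted": self.split_accepted,
            "bic_one_component": self.bic1,
            "bic_two_component": self.bic2,
            "leaf_index": self.leaf_index,
        }
        if self.split_accepted:
            d["mixing_weights"] = self.mix.tolist()
            d["children"] = [c.to_dict() for c in self.children]
        return d


def fit_beta_mixture(
    X: np.ndarray,
    sample_weights: np.ndarray | None = None,
    K: int = 2,
    seed: int | np.random.Generator = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """Weighted EM fit of a K-component per-CpG beta mixture.

    Returns ``(a, b, mix, resp, loglik)`` where ``a``/``b`` are (K, p),
    ``mix`` is (K,), ``resp`` is (n, K) and ``loglik`` is the weighted
    observed-data log-likelihood at the optimum. Best of ``n_init``
    restarts; the first restart uses a deterministic mean-split
    initialization so results do not depend on sample order for
    well-separated data.
    """
    X = _clamp(X)
    n, p = X.shape
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, float)
    if w.sum() <= 0 or n < 2:
        raise ValueError("need >= 2 samples with positive total weight")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if K == 1:
        a, b = weighted_beta_mle(X, w)
        ll = float(w @ _beta_loglik_rows(X, a, b))
        return a[None, :], b[None, :], np.ones(1), np.ones((n, 1)), ll

    best = None
    for init in range(n_init):
        if init == 0:
            # deterministic: split at the weighted median of the first
            # principal component of the logit profiles (order-invariant)
            L = np.log(X) - np.log1p(-X)
            Lc = (L - (w @ L) / w.sum()) * np.sqrt(w)[:, None]
            try:
                _, _, vt = np.linalg.svd(Lc, full_matrices=False)
                score = (L - L.mean(axis=0)) @ vt[0]
            except np.linalg.LinAlgError:
                score = X.mean(axis=1)
            pivot = _weighted_median(score, w)
            r = np.full((n, K), 0.1 / (K - 1))
            hi = score >= pivot
            r[hi, K - 1] = 0.9
            r[~hi, 0] = 0.9
        else:
            r = rng.dirichlet(np.ones(K), size=n)
        fit = _em(X, w, r, tol=tol, max_iter=max_iter)
        if fit is not None and (best is None or fit[-1] > best[-1]):
            best = fit
    if best is None:
        raise RuntimeError("EM failed on all restarts")
    return best


def _em(X, w, resp, tol, max_iter):
    n, p = X.shape
    K = resp.shape[1]
    W = w.sum()
    prev = -np.inf
    for _ in range(max_iter):
        # M step
        wk = w[:, None] * resp  # (n, K)
        mix = wk.sum(axis=0) / W
        if np.any(mix * W < 1e-8):
            return None  # component died
        a = np.empty((K, p))
        b = np.empty((K, p))
        for k in range(K):
            a[k], b[k] = weighted_beta_mle(X, wk[:, k])
        # E step
        logp = np.stack([_beta_loglik_rows(X, a[k], b[k]) for k in range(K)], axis=1)
        logp = logp + np.log(mix)[None, :]
        norm = logsumexp(logp, axis=1)
        resp = np.exp(logp - norm[:, None])
        ll = float(w @ norm)
        if ll - prev < tol * max(1.0, abs(ll)) and ll >= prev - 1e-9:
            prev = ll
            break
        prev = ll
    return a, b, mix, resp, prev


@dataclasses.dataclass
class RPMMClassing:
    """Result of a recursive beta-mixture fit."""

    root: BetaMixtureNode
    samples: pd.Index
    leaf_labels: pd.Series  # per-sample leaf class, 1..L left-to-right
    root_side: pd.Series  # per-sample "left"/"right"
    n_leaves: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"leaf_class": self.leaf_labels, "root_side": self.root_side}
        )


def rpmm_fit(
    X: pd.DataFrame | np.ndarray,
    max_depth: int = 3,
    min_node_weight: float = 2.0,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
) -> RPMMClassing:
    """Fit the recursively partitioned beta mixture.

    ``X`` is samples x CpGs. Splitting recurses to ``max_depth``; a split
    is accepted iff BIC(2 comp) < BIC(1 comp) at the node and each child
    keeps effective weight >= ``min_node_weight``. Node-level EM seeds
    derive from the node's path in the tree, so refitting a subtree is
    reproducible in isolation.
    """
    if isinstance(X, pd.DataFrame):
        samples = X.index
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        samples = pd.RangeIndex(Xv.shape[0])
    Xv = _clamp(Xv)
    n, p = Xv.shape
    if n < 4:
        root = BetaMixtureNode(name="root", sample_weight=np.ones(n))
        root.leaf_index = 1
        return RPMMClassing(
            root=root,
            samples=samples,
            leaf_labels=pd.Series(1, index=samples, name="leaf_class"),
            root_side=pd.Series("left", index=samples, name="root_side"),
            n_leaves=1,
        )

    root = BetaMixtureNode(name="root", sample_weight=np.ones(n))
    _split_node(root, Xv, depth=0, max_depth=max_depth,
                min_node_weight=min_node_weight, seed=seed, n_init=n_init, tol=tol)

    leaves: list[BetaMixtureNode] = []
    _collect_leaves(root, leaves)
    leaf_weight = np.stack([lf.sample_weight for lf in leaves], axis=1)  # (n, L)
    for i, lf in enumerate(leaves):
        lf.leaf_index = i + 1
    labels = pd.Series(np.argmax(leaf_weight, axis=1) + 1, index=samples,
                       name="leaf_class")

    if root.split_accepted:
        left_w = _subtree_weight(root.children[0])
        right_w = _subtree_weight(root.children[1])
        side = np.where(left_w >= right_w, "left", "right")  # ties -> left
    else:
        side = np.array(["left"] * n)
    root_side = pd.Series(side, index=samples, name="root_side")
    return RPMMClassing(root=root, samples=samples, leaf_labels=labels,
                        root_side=root_side, n_leaves=len(leaves))


def _subtree_weight(node: BetaMixtureNode) -> np.ndarray:
    return node.sample_weight


def _collect_leaves(node: BetaMixtureNode, out: list) -> None:
    if node.split_accepted:
        for c in node.children:
            _collect_leaves(c, out)
    else:
        out.append(node)


def _split_node(node, X, depth, max_depth, min_node_weight, seed, n_init, tol):
    w = node.sample_weight
    W = w.sum()
    n_eff = max(W, 1e-12)
    p = X.shape[1]
    active = w > 1e-8
    if depth >= max_depth or active.sum() < 2 or W < 2 * min_node_weight:
        return

    rng = stage_rng(seed, f"rpmm/{node.name}")
    a1, b1, _, _, ll1 = fit_beta_mixture(X, w, K=1, seed=rng, n_init=1, tol=tol)
    bic1 = -2.0 * ll1 + 2 * p * np.log(n_eff)
    try:
        a2, b2, mix, resp, ll2 = fit_beta_mixture(
            X, w, K=2, seed=rng, n_init=n_init, tol=tol
        )
    except RuntimeError:
        node.bic1, node.bic2 = bic1, np.inf
        return
    bic2 = -2.0 * ll2 + (4 * p + 1) * np.log(n_eff)
    node.loglik = ll2
    node.bic1, node.bic2 = float(bic1), float(bic2)

    child_w = w[:, None] * resp
    child_W = child_w.sum(axis=0)
    if not (bic2 < bic1 and np.all(child_W >= min_node_weight)):
        return

    # canonical order: less-methylated child on the left
    child_mean = np.array([
        float((a2[k] / (a2[k] + b2[k])).mean()) for k in range(2)
    ])
    order = np.argsort(child_mean, kind="stable")
    node.split_accepted = True
    node.a, node.b = a2[order], b2[order]
    node.mix, node.resp = mix[order], resp[:, order]
    node.children = []
    for pos, tag in enumerate("LR"):
        child = BetaMixtureNode(
            name=f"{node.name}.{tag}", sample_weight=child_w[:, order[pos]]
        )
        node.children.append(child)
        _split_node(child, X, depth + 1, max_depth, min_node_weight, seed,
                    n_init, tol)


def root_grouping(classing: RPMMClassing) -> pd.Series:
    """Per-sample left/right label from the root split of the RPMM tree.

    If the root did not split, every sample is "left" (degenerate
    grouping); a warning is emitted.
    """
    if not classing.root.split_accepted:
        import warnings

        warnings.warn("root split not accepted; all samples labelled 'left'")
    return classing.root_side
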