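"""Ancestral reconstruction and phylogenetic-signal statistics.

* Weighted squared-change parsimony for continuous traits (equivalent to
  the GLS / Brownian-motion point estimates): exact two-pass solver.
* dOGT: each species' OGT minus the reconstructed OGT of the most recent
  common ancestor of its genus (dOGT* generalizes to higher ranks).
* Two-state Mk model (ER or ARD) for gene presence/absence with
  maximum-likelihood rates and marginal ancestral states.
* Blomberg's K and the trait autocorrelation function over patristic
  distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .tree import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "AncestralTrait",
    "MkResult",
    "asr_squared_change",
    "compute_dogt",
    "asr_mk",
    "gene_event_shifts",
    "blomberg_k",
    "trait_acf",
]

RANK_ORDER = ("genus", "family", "order", "class", "phylum")


class MissingTipError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


def _tip_vector(tree: Phylogeny, values) -> np.ndarray:
    if isinstance(values, pd.Series):
        values = values.to_dict()
    if isinstance(values, dict):
        missing = [lab for lab in tree.tip_labels if lab not in values]
        if missing:
            raise MissingTipError(f"missing tip values for: {missing[:10]}")
        return np.array([float(values[lab]) for lab in tree.tip_labels])
    arr = np.asarray(values, dtype=float)
    if arr.size != tree.n_tips:
        raise MissingTipError("tip value vector has wrong length")
    return arr


def _safe_lengths(tree: Phylogeny, weighted: bool) -> np.ndarray:
    ln = tree.lengths.copy()
    if not weighted:
        ln[:] = 1.0
    eps = 1e-8 * max(tree.height(), 1.0)
    zero = (ln <= 0) & (np.arange(tree.n_nodes) != tree.root)
    if zero.any():
        logger.info("replacing %d zero branch lengths by %.3g", zero.sum(), eps)
        ln[zero] = eps
    return ln


# --------------------------------------------------------------------- #
#  Squared-change parsimony
# --------------------------------------------------------------------- #
@dataclass
class AncestralTrait:
    """Node values minimizing sum (x_parent - x_child)^2 / branch length."""

    values: np.ndarray  # indexed by node id
    objective: float

    def node_value(self, node: int) -> float:
        return float(self.values[node])


def asr_squared_change(
    tree: Phylogeny, tip_values, weighted: bool = True
) -> AncestralTrait:
    """Exact minimizer of the (branch-length-weighted) squared-change sum.

    Two passes over the tree: a tips-to-root elimination that condenses
    each subtree into an equivalent (value, conductance) pair, then a
    root-to-tips back-substitution. Conductance of a branch is
    1 / length; the criterion and the solution are invariant to a
    uniform rescaling of branch lengths.
    """
    x = _tip_vector(tree, tip_values)
    ln = _safe_lengths(tree, weighted)
    n = tree.n_nodes
    G = np.zeros(n)  # combined child conductance at a node
    V = np.zeros(n)  # combined child value at a node
    g_up = np.zeros(n)  # conductance presented to the parent
    v_up = np.zeros(n)
    for node in tree.postorder:
        if tree.is_tip(node):
            g_up[node] = 1.0 / ln[node]
            v_up[node] = x[node]
            continue
        gs = g_up[tree.children[node]]
        vs = v_up[tree.children[node]]
        G[node] = gs.sum()
        V[node] = float(gs @ vs) / G[node]
        if node != tree.root:
            g_up[node] = 1.0 / (ln[node] + 1.0 / G[node])
            v_up[node] = V[node]
    vals = np.empty(n)
    vals[: tree.n_tips] = x
    above_g = np.zeros(n)  # conductance of the rest of the tree, seen from a node
    above_v = np.zeros(n)
    vals[tree.root] = V[tree.root]
    for node in tree.preorder:
        if tree.is_tip(node) and node != tree.root:
            continue
        ag, av = above_g[node], above_v[node]
        if node != tree.root:
            vals[node] = (G[node] * V[node] + ag * av) / (G[node] + ag)
        for child in tree.children[node]:
            g_rest = G[node] - g_up[child] + ag
            if g_rest <= 0:
                above_g[child] = 0.0
                above_v[child] = vals[node]
                continue
            v_rest = (
                G[node] * V[node] - g_up[child] * v_up[child] + ag * av
            ) / g_rest
            above_g[child] = 1.0 / (ln[child] + 1.0 / g_rest)
            above_v[child] = v_rest
    nodes = np.arange(n)
    mask = nodes != tree.root
    obj = float(
        (((vals[tree.parent[mask]] - vals[mask]) ** 2) / ln[mask]).sum()
    )
    return AncestralTrait(vals, obj)


# --------------------------------------------------------------------- #
#  dOGT / dOGT*
# --------------------------------------------------------------------- #
def compute_dogt(
    tree: Phylogeny,
    ogt,
    taxonomy: pd.DataFrame,
    ranks: tuple[str, ...] = RANK_ORDER,
    min_clade_size: int = 5,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-species OGT change from the reconstructed rank ancestors.

    The ancestor value is the squared-change-parsimony reconstruction at
    the MRCA of each named clade; ``dOGT = OGT_current - OGT_ancestor``.
    Clades with <= ``min_clade_size`` species are skipped. Non-monophyletic
    named clades are logged and represented by their MRCA.
    """
    for rank in ranks:
        if rank not in taxonomy.columns:
            raise ValueError(f"rank {rank!r} absent from taxonomy")
    tax = taxonomy.set_index("species_id")
    anc = asr_squared_change(tree, ogt, weighted=weighted)
    ogt_map = ogt.to_dict() if isinstance(ogt, pd.Series) else dict(ogt)
    rows = []
    for rank in ranks:
        for taxon, members in tax.groupby(rank).groups.items():
            labels = [m for m in members if m in tree.tip_index]
            if len(labels) <= min_clade_size:
                continue
            tips = [tree.tip_index[m] for m in labels]
            node = tree.mrca(tips)
            clade = tree.subtree_tips(node)
            if len(clade) != len(tips):
                logger.info(
                    "clade %s (%s) not monophyletic: %d tips vs %d in MRCA subtree",
                    taxon, rank, len(tips), len(clade),
                )
            anc_val = anc.node_value(node)
            for lab in labels:
                rows.append(
                    {
                        "species_id": lab,
                        "rank": rank,
                        "taxon": taxon,
                        "ogt": float(ogt_map[lab]),
                        "ancestor_ogt": anc_val,
                        "dogt": float(ogt_map[lab]) - anc_val,
                        "clade_size": len(labels),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "rank", "taxon", "ogt", "ancestor_ogt", "dogt", "clade_size",
        ],
    )


# --------------------------------------------------------------------- #
#  Mk model
# --------------------------------------------------------------------- #
@dataclass
class MkResult:
    """Fitted two-state Mk model and marginal ancestral reconstructions."""

    q01: float  # gain rate (0 -> 1)
    q10: float  # loss rate (1 -> 0)
    log_likelihood: float
    marginals: np.ndarray  # (n_nodes, 2); tips are one-hot at their state
    model: str = "ER"
    degenerate: bool = False
    root_prior: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))


def _transition(q01: float, q10: float, t: np.ndarray) -> np.ndarray:
    """Analytic 2-state transition matrices for each branch length."""
    s = q01 + q10
    e = np.exp(-s * t)
    pi0 = q10 / s
    pi1 = q01 / s
    P = np.empty((t.size, 2, 2))
    P[:, 0, 0] = pi0 + pi1 * e
    P[:, 0, 1] = pi1 * (1 - e)
    P[:, 1, 0] = pi0 * (1 - e)
    P[:, 1, 1] = pi1 + pi0 * e
    return P


def _mk_up(tree: Phylogeny, states: np.ndarray, P: np.ndarray):
    """Pruning pass: per-node partial likelihoods with log scaling."""
    n = tree.n_nodes
    up = np.zeros((n, 2))
    logscale = np.zeros(n)
    up[np.arange(tree.n_tips), states] = 1.0
    for node in tree.postorder:
        if tree.is_tip(node):
            continue
        vec = np.ones(2)
        ls = 0.0
        for c in tree.children[node]:
            vec = vec * (P[c] @ up[c])
            ls += logscale[c]
        m = vec.max()
        up[node] = vec / m
        logscale[node] = ls + np.log(m)
    return up, logscale


def _mk_loglik(
    tree: Phylogeny, states: np.ndarray, q01: float, q10: float, prior: np.ndarray
) -> float:
    P = _transition(q01, q10, tree.lengths)
    up, logscale = _mk_up(tree, states, P)
    r = tree.root
    like = float(prior @ up[r])
    if like <= 0:
        return -np.inf
    return float(np.log(like) + logscale[r])


def asr_mk(
    tree: Phylogeny,
    tip_states,
    rate_model: str = "ER",
    root_prior: str = "stationary",
) -> MkResult:
    """Fit a 2-state Mk model and reconstruct marginal node states.

    Rates are estimated by maximum likelihood (pruning algorithm, bounded
    optimization over log rates); marginal reconstructions use the
    rerooting recursion. The root prior is the stationary distribution of
    the fitted chain (or flat with ``root_prior='flat'``).
    """
    states = _tip_vector(tree, tip_states).astype(np.int64)
    if not np.isin(states, (0, 1)).all():
        raise ValueError("tip states must be binary 0/1")
    degenerate = states.min() == states.max()

    def prior_of(a: float, b: float) -> np.ndarray:
        if root_prior == "flat":
            return np.array([0.5, 0.5])
        return np.array([b, a]) / (a + b)

    lo, hi = np.log(1e-6), np.log(50.0)
    if degenerate:
        # no information about rates: pin them at the lower boundary
        a = b = float(np.exp(lo))
    elif rate_model == "ER":
        res = optimize.minimize_scalar(
            lambda u: -_mk_loglik(
                tree, states, np.exp(u), np.exp(u), prior_of(np.exp(u), np.exp(u))
            ),
            bounds=(lo, hi),
            method="bounded",
        )
        a = b = float(np.exp(res.x))
    elif rate_model == "ARD":
        best = None
        for u0 in (np.log(0.05), np.log(0.5)):
            res = optimize.minimize(
                lambda u: -_mk_loglik(
                    tree, states, np.exp(u[0]), np.exp(u[1]),
                    prior_of(np.exp(u[0]), np.exp(u[1])),
                ),
                x0=np.array([u0, u0]),
                bounds=[(lo, hi), (lo, hi)],
                method="L-BFGS-B",
            )
            if best is None or res.fun < best.fun:
                best = res
        a, b = (float(np.exp(v)) for v in best.x)
    else:
        raise ValueError(f"unknown rate model: {rate_model!r}")

    prior = prior_of(a, b)
    P = _transition(a, b, tree.lengths)
    up, logscale = _mk_up(tree, states, P)
    loglik = _mk_loglik(tree, states, a, b, prior)

    # rerooting / down-pass marginals
    n = tree.n_nodes
    down = np.zeros((n, 2))
    down[tree.root] = prior
    for node in tree.preorder:
        if tree.is_tip(node):
            continue
        msgs = {c: P[c] @ up[c] for c in tree.children[node]}
        for c in tree.children[node]:
            rest = down[node].copy()
            for s in tree.children[node]:
                if s != c:
                    rest = rest * msgs[s]
            d = rest @ P[c]
            tot = d.sum()
            down[c] = d / tot if tot > 0 else np.array([0.5, 0.5])
    marg = up * down
    tot = marg.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    marg = marg / tot
    marg[np.arange(tree.n_tips)] = 0.0
    marg[np.arange(tree.n_tips), states] = 1.0
    return MkResult(a, b, loglik, marg, rate_model, degenerate, prior)


# --------------------------------------------------------------------- #
#  Gain/loss events vs OGT shifts
# --------------------------------------------------------------------- #
def gene_event_shifts(
    tree: Phylogeny,
    mk: MkResult,
    anc: AncestralTrait,
    tip_states,
    tip_ogt,
) -> dict:
    """Map inferred gain/loss branches to reconstructed OGT changes.

    Each node takes its max-marginal state (ties resolved to the parent's
    state; tips fixed to their observed state). A branch whose parent and
    child states differ is a gain (0 -> 1) or loss (1 -> 0), and its OGT
    shift is the child's reconstructed value (or observed tip OGT) minus
    the parent's reconstruction.
    """
    states = _tip_vector(tree, tip_states).astype(np.int64)
    ogt = _tip_vector(tree, tip_ogt)
    assign = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.preorder:
        if tree.is_tip(node):
            assign[node] = states[node]
            continue
        m = mk.marginals[node]
        if np.isclose(m[0], m[1]):
            p = tree.parent[node]
            assign[node] = assign[p] if p >= 0 else int(m[1] >= m[0])
        else:
            assign[node] = int(m[1] > m[0])
    value = anc.values.copy()
    value[: tree.n_tips] = ogt
    events = []
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0 or assign[node] == assign[p]:
            continue
        events.append(
            {
                "node": node,
                "event": "gain" if assign[node] == 1 else "loss",
                "delta_ogt": float(value[node] - value[p]),
            }
        )
    ev = pd.DataFrame(events, columns=["node", "event", "delta_ogt"])
    gains = ev[ev["event"] == "gain"]["delta_ogt"]
    losses = ev[ev["event"] == "loss"]["delta_ogt"]
    return {
        "n_gains": int(len(gains)),
        "n_losses": int(len(losses)),
        "gain_mean_shift": float(gains.mean()) if len(gains) else np.nan,
        "loss_mean_shift": float(losses.mean()) if len(losses) else np.nan,
        "events": ev,
    }


# --------------------------------------------------------------------- #
#  Phylogenetic signal
# --------------------------------------------------------------------- #
def blomberg_k(tree: Phylogeny, trait) -> float:
    """Blomberg's K: observed vs Brownian-expected MSE0/MSE ratio.

    K is about 1 for traits evolved under Brownian motion on the tree and
    much smaller when trait variation is independent of phylogeny. The
    statistic is invariant to affine transformations of the trait.
    """
    x = _tip_vector(tree, trait)
    n = x.size
    if n < 4:
        raise UndefinedStatisticError("need at least 4 tips")
    if np.allclose(x, x[0]):
        raise UndefinedStatisticError("trait is constant")
    C = tree.mrca_depth_matrix()
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = float(one @ Cinv @ one)
    ahat = float(one @ Cinv @ x) / denom
    dev = x - ahat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Cinv @ dev) / (n - 1)
    observed = mse0 / mse
    expected = (np.trace(C) - n / denom) / (n - 1)
    return float(observed / expected)


def trait_acf(tree: Phylogeny, trait, n_bins: int = 10) -> pd.DataFrame:
    """Tip-pair trait correlation as a function of patristic distance.

    All unordered tip pairs are placed into ``n_bins`` equal-count bins
    by patristic distance; each bin reports the Pearson correlation over
    symmetrized pairs (each pair contributes both orderings), the mean
    distance, and the pair count.
    """
    x = _tip_vector(tree, trait)
    if x.size < 4:
        raise UndefinedStatisticError("need at least 4 tips")
    if np.allclose(x, x[0]):
        raise UndefinedStatisticError("trait is constant")
    D = tree.patristic_matrix()
    iu = np.triu_indices(x.size, k=1)
    d = D[iu]
    if d.size < n_bins:
        raise ValueError("fewer tip pairs than bins")
    order = np.argsort(d, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        a = x[iu[0][chunk]]
        b = x[iu[1][chunk]]
        u = np.concatenate([a, b])
        v = np.concatenate([b, a])
        su = u.std()
        corr = np.nan if su == 0 else float(
            ((u - u.mean()) @ (v - v.mean())) / (u.size * u.std() * v.std())
        )
        rows.append(
            {
                "mean_distance": float(d[chunk].mean()),
                "correlation": corr,
                "n_pairs": int(chunk.size),
            }
        )
    return pd.DataFrame(rows)
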