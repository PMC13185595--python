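"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by brute force (enumeration, direct
linear algebra, exact combinatorics) along a code path disjoint from the
package implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy import optimize


# --------------------------------------------------------------------- #
#  Squared-change parsimony: generic numeric minimization
# --------------------------------------------------------------------- #
def scp_numeric(tree, x: np.ndarray) -> np.ndarray:
    """Minimize the weighted squared-change sum with a generic optimizer."""
    internal = np.arange(tree.n_tips, tree.n_nodes)
    idx = {n: i for i, n in enumerate(internal)}
    mask = np.arange(tree.n_nodes) != tree.root
    w = 1.0 / tree.lengths[mask]
    par = tree.parent[mask]
    nod = np.arange(tree.n_nodes)[mask]

    def fg(v):
        vals = np.empty(tree.n_nodes)
        vals[: tree.n_tips] = x
        vals[internal] = v
        diff = vals[par] - vals[nod]
        g = np.zeros(tree.n_nodes)
        np.add.at(g, par, 2 * w * diff)
        np.add.at(g, nod, -2 * w * diff)
        return (w * diff**2).sum(), g[internal]

    def hess(v):
        H = np.zeros((internal.size, internal.size))
        for p_, n_, w_ in zip(par, nod, w):
            pi, ni = idx.get(p_), idx.get(n_)
            if pi is not None:
                H[pi, pi] += 2 * w_
            if ni is not None:
                H[ni, ni] += 2 * w_
            if pi is not None and ni is not None:
                H[pi, ni] -= 2 * w_
                H[ni, pi] -= 2 * w_
        return H

    res = optimize.minimize(
        fg, np.full(internal.size, x.mean()), jac=True, hess=hess,
        method="trust-exact",
    )
    out = np.empty(tree.n_nodes)
    out[: tree.n_tips] = x
    out[internal] = res.x
    return out


# --------------------------------------------------------------------- #
#  Mk likelihood: direct sum over all internal-state assignments
# --------------------------------------------------------------------- #
def mk_exhaustive_loglik(tree, states, q01: float, q10: float, prior) -> float:
    s = q01 + q10
    pi0, pi1 = q10 / s, q01 / s

    def pmat(t):
        e = np.exp(-s * t)
        return np.array(
            [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
        )

    internal = list(range(tree.n_tips, tree.n_nodes))
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, combo))
        for i, v in enumerate(states):
            st[i] = int(v)
        like = prior[st[tree.root]]
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            if p >= 0:
                like *= pmat(tree.lengths[node])[st[p], st[node]]
        total += like
    return float(np.log(total))


# --------------------------------------------------------------------- #
#  Fisher's exact test: exact rational enumeration
# --------------------------------------------------------------------- #
def fisher_exact_enumeration(a: int, b: int, c: int, d: int):
    """(two-sided, less, greater) p's for [[a, b], [c, d]], exact fractions.

    Enumerates every table with the same margins; the two-sided p sums
    outcomes whose hypergeometric probability does not exceed the
    observed one (with a tiny relative tolerance for ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    two = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
    less = sum(v for k, v in probs.items() if k <= a)
    greater = sum(v for k, v in probs.items() if k >= a)
    return two / denom, less / denom, greater / denom


# --------------------------------------------------------------------- #
#  RNA pairing score: explicit enumeration of all nested structures
# --------------------------------------------------------------------- #
_PAIR_W = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0, ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0, ("G", "T"): 1.0, ("T", "G"): 1.0,
}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every valid nested structure as a frozenset of (i, j) pairs."""
    seq = seq.upper()

    def gen(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        j = positions[-1]
        # j unpaired
        for s in gen(positions[:-1]):
            yield s
        # j paired with an earlier k, splitting the region (nestedness)
        for ki, k in enumerate(positions[:-1]):
            if j - k <= min_loop:
                continue
            if (seq[k], seq[j]) not in _PAIR_W:
                continue
            inside = tuple(p for p in positions[ki + 1 : -1] if p > k)
            outside = tuple(p for p in positions[:ki])
            for s_in in gen(inside):
                for s_out in gen(outside):
                    yield s_in | s_out | {(k, j)}

    yield from gen(tuple(range(len(seq))))


def best_structure_enumeration(seq: str, min_loop: int = 3) -> float:
    """Maximum total pair weight over explicitly enumerated structures."""
    seq = seq.upper()
    best = 0.0
    for s in enumerate_structures(seq, min_loop):
        w = sum(_PAIR_W[(seq[i], seq[j])] for i, j in s)
        best = max(best, w)
    return float(best)


# --------------------------------------------------------------------- #
#  Tukey HSD from first principles
# --------------------------------------------------------------------- #
def tukey_hsd_manual(samples: list[np.ndarray], alpha: float = 0.05):
    """Pairwise mean differences with studentized-range CIs."""
    from scipy.stats import studentized_range

    k = len(samples)
    ns = [len(s) for s in samples]
    means = [float(np.mean(s)) for s in samples]
    df = sum(ns) - k
    mse = sum(((s - m) ** 2).sum() for s, m in zip(samples, means)) / df
    q = studentized_range.ppf(1 - alpha, k, df)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
            half = q / np.sqrt(2) * se * np.sqrt(2)
            # q already refers to the range statistic: CI = diff +/- q*se
            half = q * se
            out.append((i, j, diff, diff - half, diff + half))
    return out
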