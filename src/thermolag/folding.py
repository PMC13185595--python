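"""Structural-RNA stability scores.

The built-in engine is a Nussinov-style dynamic program that maximizes a
weighted count of nested base pairs (GC=3, AU=2, GU=1 by default, with a
minimum hairpin loop of 3 unpaired bases) and reports the negated optimum
as a dimensionless energy, so more stable sequences score more negative.
An external engine can delegate to any folding command (e.g. RNAfold)
that prints a free energy; it is never used silently as a fallback.
"""

from __future__ import annotations

import re
import shutil
import subprocess

import numpy as np

__all__ = ["fold_energy", "ConfigurationError"]


class ConfigurationError(RuntimeError):
    pass


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

DEFAULT_WEIGHTS = {("G", "C"): 3.0, ("A", "U"): 2.0, ("G", "U"): 1.0}
MIN_LOOP = 3


def _weight_matrix(weights: dict[tuple[str, str], float]) -> np.ndarray:
    W = np.zeros((4, 4))
    for (a, b), w in weights.items():
        W[_BASE_INDEX[a], _BASE_INDEX[b]] = w
        W[_BASE_INDEX[b], _BASE_INDEX[a]] = w
    return W


def _nussinov_py(idx: np.ndarray, W: np.ndarray, min_loop: int) -> float:
    n = idx.size
    dp = np.zeros((n, n))
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = dp[i + 1, j]
            w = W[idx[i], idx[j]]
            if w > 0:
                best = max(best, dp[i + 1, j - 1] + w)
            for k in range(i, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return float(dp[0, n - 1])


try:  # pragma: no cover - exercised whenever numba is importable
    import numba

    _nussinov_fast = numba.njit(cache=False)(_nussinov_py)
except Exception:  # pragma: no cover
    _nussinov_fast = None


def fold_energy(
    rna: str,
    engine: str = "builtin",
    weights: dict[tuple[str, str], float] | None = None,
    min_loop: int = MIN_LOOP,
    external_cmd: list[str] | None = None,
) -> float:
    """Score of the most stable secondary structure of ``rna`` (<= 0).

    Parameters
    ----------
    rna
        RNA or DNA sequence (T is read as U).
    engine
        ``"builtin"`` for the weighted base-pair maximization, or
        ``"external"`` to run ``external_cmd`` with the sequence on stdin
        and parse the last parenthesized float of its output (the RNAfold
        convention).
    """
    seq = rna.strip().upper()
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    bad = set(seq) - set(_BASE_INDEX)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if engine == "external":
        return _external_energy(seq, external_cmd)
    if engine != "builtin":
        raise ConfigurationError(f"unknown folding engine: {engine!r}")
    W = _weight_matrix(weights or DEFAULT_WEIGHTS)
    idx = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    if idx.size <= min_loop + 1:
        return 0.0
    if _nussinov_fast is not None:
        return -float(_nussinov_fast(idx, W, min_loop))
    return -_nussinov_py(idx, W, min_loop)


def _external_energy(seq: str, cmd: list[str] | None) -> float:
    if not cmd:
        raise ConfigurationError(
            "engine='external' requires external_cmd (e.g. ['RNAfold', '--noPS'])"
        )
    if shutil.which(cmd[0]) is None:
        raise ConfigurationError(f"external folding command not found: {cmd[0]}")
    out = subprocess.run(
        cmd, input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout
    matches = re.findall(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)", out)
    if not matches:
        raise ConfigurationError(f"could not parse an energy from: {out!r}")
    return float(matches[-1])
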