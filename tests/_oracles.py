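"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: naive O(n^3) UPGMA,
exhaustive hypergeometric-table enumeration, hand-rolled BH, and full
enumeration of permutation q-values on tiny designs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def upgma_heights(points: np.ndarray) -> list[float]:
    """Naive average-linkage clustering; returns sorted merge heights.

    Inter-cluster distance is the mean of all pairwise Euclidean distances
    between members (computed from scratch each round).
    """
    clusters: list[list[int]] = [[i] for i in range(len(points))]

    def dist(a: list[int], b: list[int]) -> float:
        return float(
            np.mean([np.linalg.norm(points[i] - points[j]) for i in a for j in b])
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        heights.append(d)
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return sorted(heights)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by summing over all more-extreme tables."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Textbook step-up Benjamini-Hochberg, written longhand."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * n / rank_from_top)
        adj[i] = running
    return adj


def welch_d(values: np.ndarray, treated: np.ndarray, s0: float) -> np.ndarray:
    """Straightforward per-protein moderated statistic (loop, no shortcuts)."""
    out = []
    for row in values:
        a, b = row[treated], row[~treated]
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        delta = a.mean() - b.mean()
        out.append(delta / (se + s0) if se + s0 > 0 else 0.0)
    return np.array(out)


def enumerate_permutation_q(values: np.ndarray, treated: np.ndarray, s0: float) -> np.ndarray:
    """q-values from ALL distinct non-identity group assignments.

    Mirrors the estimator's definition (mean null exceedance over observed
    exceedance, monotone in |d|) but enumerates every assignment explicitly
    and computes every count with python loops.
    """
    n = len(treated)
    n1 = int(treated.sum())
    d_obs = np.abs(welch_d(values, treated, s0))
    identity = tuple(np.flatnonzero(treated))
    null_abs = []
    for combo in itertools.combinations(range(n), n1):
        if combo == identity:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        null_abs.append(np.abs(welch_d(values, mask, s0)))
    B = len(null_abs)
    q = np.empty(len(d_obs))
    for i, t in enumerate(d_obs):
        ev = sum((arr >= t).sum() for arr in null_abs) / B
        r = int((d_obs >= t).sum())
        q[i] = min(1.0, ev / r)
    # monotone enforcement: bigger |d| never gets a bigger q
    order = np.argsort(-d_obs, kind="stable")
    qs = q[order]
    for i in range(len(qs) - 2, -1, -1):
        qs[i] = min(qs[i], qs[i + 1])
    out = np.empty_like(q)
    out[order] = qs
    return out
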