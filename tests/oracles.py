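"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration, two-pass
formulas, step-by-step agglomeration — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import comb
from scipy.stats import rankdata


def two_pass_zscore(row: np.ndarray) -> np.ndarray:
    mean = sum(row) / len(row)
    var = sum((x - mean) ** 2 for x in row) / (len(row) - 1)
    return (np.asarray(row) - mean) / np.sqrt(var)


def rank_then_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx**2).sum() * (ry**2).sum()))


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration of the hypergeometric
    support with exact binomial coefficients."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {
        k: comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def mw_exact_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p: doubling of the smaller tail over
    all C(n, n_a) group labelings."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = [
        ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        for idx in combinations(range(len(pooled)), n_a)
    ]
    us = np.asarray(us)
    lower = np.mean(us <= u_obs + 1e-12)
    upper = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lower, upper))


def mw_permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int, seed: int) -> float:
    """Monte-Carlo permutation estimate of the two-sided Mann-Whitney p
    (doubling convention) with average ranks."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    offset = n_a * (n_a + 1) / 2
    u_obs = ranks[:n_a].sum() - offset
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)[:, :n_a]
    us = ranks[idx].sum(axis=1) - offset
    lower = np.mean(us <= u_obs + 1e-12)
    upper = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lower, upper))


def brute_force_centroid_merges(points: np.ndarray):
    """Step-by-step centroid agglomeration recomputing every pairwise
    centroid distance at each step; returns the merge list in the same
    (node_a, node_b, height, size) convention, ties broken by smallest
    (first-node, second-node) pair."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_node = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i_pos in range(len(keys)):
            for j_pos in range(i_pos + 1, len(keys)):
                ki, kj = keys[i_pos], keys[j_pos]
                ci = points[clusters[ki]].mean(axis=0)
                cj = points[clusters[kj]].mean(axis=0)
                dist = float(np.linalg.norm(ci - cj))
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, ki, kj)
        dist, ki, kj = best
        members = clusters.pop(ki) + clusters.pop(kj)
        merges.append((ki, kj, dist, len(members)))
        clusters[next_node] = members
        next_node += 1
    return merges


def km_by_hand(times: np.ndarray, events: np.ndarray):
    """Spreadsheet-style product-limit recomputation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s = s * (n_t - d_t) / n_t
        out.append((t, n_t, d_t, s))
    return out
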