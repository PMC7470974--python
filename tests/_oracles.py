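"""Independent brute-force reference implementations used by the tests.

Each oracle is deliberately naive (enumeration, O(n^2) scans, closed forms)
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def chain_merge(positions: list[int], max_gap: int) -> list[list[int]]:
    """Single-linkage chaining of sorted positions by pairwise distance,
    computed transitively from the full distance relation."""
    positions = sorted(positions)
    groups: list[list[int]] = []
    for p in positions:
        placed = None
        for g in groups:
            if any(abs(p - q) <= max_gap for q in g):
                placed = g
                break
        if placed is None:
            groups.append([p])
        else:
            placed.append(p)
    # transitive closure: merge groups linked through later additions
    changed = True
    while changed:
        changed = False
        for a, b in combinations(range(len(groups)), 2):
            if any(abs(p - q) <= max_gap for p in groups[a] for q in groups[b]):
                groups[a].extend(groups.pop(b))
                changed = True
                break
    return sorted([sorted(g) for g in groups])


def interval_merge(intervals: list[tuple[int, int]],
                   max_gap: int) -> list[tuple[int, int]]:
    """Transitive merge of inclusive intervals by repeated pairwise joining."""
    work = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for a, b in combinations(range(len(work)), 2):
            (s1, e1), (s2, e2) = work[a], work[b]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                work[a] = [min(s1, s2), max(e1, e2)]
                work.pop(b)
                changed = True
                break
    return sorted(tuple(iv) for iv in work)


def quantile_bounds(positions, weights, low=0.1, high=0.9):
    """10th/90th expression percentile positions by explicit scanning."""
    total = sum(weights)
    cum = 0.0
    q_low = q_high = None
    for p, w in zip(positions, weights):
        cum += w
        if q_low is None and cum >= low * total:
            q_low = p
        if q_high is None and cum >= high * total:
            q_high = p
    return q_low, q_high


def pwm_scan(freqs: np.ndarray, seq: str, background: float = 0.25):
    """Per-offset min-max scaled log2-odds match percents, rescored naively."""
    L = len(freqs)
    logodds = np.log2(freqs / background)
    mx = sum(max(logodds[i]) for i in range(L))
    mn = sum(min(logodds[i]) for i in range(L))
    out = []
    for start in range(len(seq) - L + 1):
        score = 0.0
        for i, base in enumerate(seq[start:start + L]):
            score += logodds[i]["ACGT".index(base)] if base in "ACGT" \
                else min(logodds[i])
        out.append(100.0 * (score - mn) / (mx - mn))
    return np.array(out)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of the hypergeometric
    support at fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_prob(x):
        return (_lchoose(row1, x) + _lchoose(n - row1, col1 - x)
                - _lchoose(n, col1))

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    probs = {x: math.exp(log_prob(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def _lchoose(n, k):
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def bh_stepup(pvals):
    """Benjamini-Hochberg by the textbook step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(prev, pvals[i] * m / rank)
        adj[i] = value
        prev = value
    return adj


def least_squares(x, y):
    """Closed-form simple linear regression (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return slope, ybar - slope * xbar


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))
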