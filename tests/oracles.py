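"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — explicit loops and enumeration,
no shared code with the package — so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def brute_logrank(times_a, events_a, times_b, events_b):
    """Textbook two-sample log-rank by explicit per-event-time tabulation.

    Returns (statistic, p, sum_oe_b) where sum_oe_b is the summed observed
    minus expected deaths in group b.
    """
    t = list(times_a) + list(times_b)
    e = list(events_a) + list(events_b)
    g = [0] * len(times_a) + [1] * len(times_b)
    event_times = sorted({ti for ti, ei in zip(t, e) if ei})
    sum_oe = 0.0
    sum_v = 0.0
    for u in event_times:
        n = sum(1 for ti in t if ti >= u)
        n_b = sum(1 for ti, gi in zip(t, g) if gi == 1 and ti >= u)
        d = sum(1 for ti, ei in zip(t, e) if ei and ti == u)
        d_b = sum(
            1 for ti, ei, gi in zip(t, e, g) if gi == 1 and ei and ti == u
        )
        sum_oe += d_b - d * n_b / n
        if n > 1:
            sum_v += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    if sum_v <= 0:
        return 0.0, 1.0, sum_oe
    stat = sum_oe**2 / sum_v
    return stat, float(stats.chi2.sf(stat, df=1)), sum_oe


def km_by_hand(times, events):
    """Product-limit estimate via explicit per-time (1 - d/n) products.

    Returns (event_times, survival_probs).
    """
    event_times = sorted({t for t, e in zip(times, events) if e})
    s = 1.0
    probs = []
    for u in event_times:
        n = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if e and t == u)
        s *= 1 - d / n
        probs.append(s)
    return event_times, probs


def bh_stepup(p_values):
    """BH q-values straight from the step-up definition:
    q_i = min over j with p_(j) >= p_i of m * p_(j) / j, clipped at 1."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    qs = [0.0] * m
    for i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[i]
        ]
        qs[i] = min(1.0, min(candidates))
    return qs


def chi2_2x2(a, b, c, d):
    """Closed-form Pearson chi-square of a 2x2 table, no correction."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def hypergeom_tail_enum(k, universe_size, n_successes, n_draws):
    """P(overlap >= k) by exhaustive enumeration of all draws (N <= 12)."""
    universe = list(range(universe_size))
    successes = set(universe[:n_successes])
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n_draws):
        total += 1
        if len(successes & set(draw)) >= k:
            hits += 1
    return hits / total


def step_mse_scan(values):
    """Exhaustive step-fit scan over all midpoints between consecutive
    distinct sorted values; returns the minimal within-group MSE."""
    v = np.sort(np.asarray(values, dtype=float))
    distinct = np.unique(v)
    best = np.inf
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = (lo + hi) / 2
        low, high = v[v <= t], v[v > t]
        mse = (
            np.sum((low - low.mean()) ** 2) + np.sum((high - high.mean()) ** 2)
        ) / v.size
        best = min(best, mse)
    return best
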