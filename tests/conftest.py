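"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no panprobio internals)

def n50_oracle(lengths):
    """Cumulative brute force: smallest L with sum(lengths >= L) >= half."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) >= total / 2:
            return L
    raise AssertionError("unreachable")


def ranksum_p_oracle(x, y):
    """Exact two-sided p by enumerating all C(n, nx) group labelings of the
    pooled tie-free sample and comparing rank sums."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    nx = len(x)
    obs = sum(ranks[v] for v in x)
    mean = nx * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, nx):
        stat = sum(ranks[v] for v in combo)
        total += 1
        if abs(stat - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def pearson_oracle(x, y):
    """Closed-form covariance / variance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def bh_oracle(ps):
    """Textbook BH step-up with monotone minimum from the largest p down."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, ps[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def cross_pairs_oracle(strains_by_species):
    """Explicit double loop over all strains."""
    flat = [(s, g) for s, gs in strains_by_species.items() for g in gs]
    count = 0
    for (sa, _), (sb, _) in itertools.combinations(flat, 2):
        if sa != sb:
            count += 1
    return count


def complementarity_oracle(kos_a, kos_b, modules):
    """Recompute the improvement ratio by explicit per-module set counting."""
    def total(kos):
        return sum(len(set(kos) & set(m.required_kos)) / len(m.required_kos)
                   for m in modules)

    t_a, t_b = total(kos_a), total(kos_b)
    t_m = total(set(kos_a) | set(kos_b))
    base = max(t_a, t_b)
    if base == 0:
        return 0.0 if t_m == 0 else math.inf
    return (t_m - base) / base
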