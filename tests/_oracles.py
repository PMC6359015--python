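"""Independent reference implementations used only by the tests.

Everything here is deliberately written from first principles (loops,
exact arithmetic, literal rule lists) and shares no code with the package,
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import scipy.stats

STATUSES = ("up", "down", "ns")

_PRECEDENCE = (
    "shared_same",
    "shared_opposite",
    "required",
    "corrected",
    "genotype_dependent",
    "compensated",
    "persistent_genotype_difference",
)


def literal_category_matches(pattern):
    """All named categories whose defining criteria the pattern meets.

    Each criteria list is transcribed literally, one boolean clause per
    stated condition, with no precedence applied.
    """
    wt_vert, ko_vert, ground_horiz, flight_horiz = pattern
    matches = []
    # both genotypes respond, same direction
    if wt_vert in ("up", "down") and ko_vert in ("up", "down") and wt_vert == ko_vert:
        matches.append("shared_same")
    # both respond, opposite directions
    if wt_vert in ("up", "down") and ko_vert in ("up", "down") and wt_vert != ko_vert:
        matches.append("shared_opposite")
    # WT responds to flight; genotypes differ on the ground; KO does not
    # respond; genotypes match in flight
    if (
        wt_vert in ("up", "down")
        and ground_horiz in ("up", "down")
        and ko_vert == "ns"
        and flight_horiz == "ns"
    ):
        matches.append("required")
    # KO responds; genotypes differ on the ground; WT does not respond;
    # genotypes match in flight
    if (
        ko_vert in ("up", "down")
        and ground_horiz in ("up", "down")
        and wt_vert == "ns"
        and flight_horiz == "ns"
    ):
        matches.append("corrected")
    # only WT responds; no ground difference; flight difference appears
    if (
        wt_vert in ("up", "down")
        and ko_vert == "ns"
        and ground_horiz == "ns"
        and flight_horiz in ("up", "down")
    ):
        matches.append("genotype_dependent")
    # only KO responds; no ground difference; flight difference appears
    if (
        ko_vert in ("up", "down")
        and wt_vert == "ns"
        and ground_horiz == "ns"
        and flight_horiz in ("up", "down")
    ):
        matches.append("compensated")
    # genotypes differ the same way on the ground and in flight
    if (
        ground_horiz in ("up", "down")
        and flight_horiz in ("up", "down")
        and ground_horiz == flight_horiz
    ):
        matches.append("persistent_genotype_difference")
    return matches


def brute_force_classify(pattern):
    """Literal rule checking plus the stated precedence order."""
    matches = literal_category_matches(pattern)
    for category in _PRECEDENCE:
        if category in matches:
            return category
    if any(s in ("up", "down") for s in pattern):
        return "other_pattern"
    return "none"


def all_patterns():
    """All 81 status 4-tuples."""
    return [
        (a, b, c, d)
        for a in STATUSES
        for b in STATUSES
        for c in STATUSES
        for d in STATUSES
    ]


def pooled_t_oracle(values, groups, first, second):
    """Two-sample t-test with the variance pooled over all design cells.

    ``values``: gene x sample ndarray; ``groups``: list of per-sample
    (genotype, environment) labels; ``first``/``second``: the two cells
    being contrasted. Returns (estimate, t, two-sided p) per gene, computed
    with explicit loops over cells and scipy's t distribution only.
    """
    values = np.asarray(values, dtype=float)
    cells = sorted(set(groups))
    n_total = values.shape[1]
    rss = np.zeros(values.shape[0])
    means = {}
    for cell in cells:
        idx = [j for j, g in enumerate(groups) if g == cell]
        sub = values[:, idx]
        mu = sub.mean(axis=1)
        means[cell] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df = n_total - len(cells)
    s2 = rss / df
    n1 = sum(1 for g in groups if g == first)
    n2 = sum(1 for g in groups if g == second)
    estimate = means[first] - means[second]
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    t = estimate / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=df)
    return estimate, t, p


def bh_step_up_oracle(p_values):
    """Benjamini-Hochberg by the textbook recipe: sort, p*(m/i), cummin."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def hypergeom_upper_tail_exact(k, N, K, n):
    """P(X >= k) for Hypergeometric(N, K, n) by exact rational summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)
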