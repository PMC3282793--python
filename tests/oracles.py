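"""Independent brute-force oracles used by the test suite.

Everything here is written as naively as possible (character loops, full
enumeration) and shares no code with the package implementation it checks.
"""

import math
from itertools import combinations, product

UNAMBIG = set("ACGT")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def pair_distance_oracle(seq_a: str, seq_b: str, model: str):
    """(distance, comparable_sites) by direct per-character inspection.

    Returns the string "saturated" in place of a K2P distance when the log
    argument is non-positive, and "undefined" when no site is comparable.
    """
    ts = tv = n = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in UNAMBIG and y in UNAMBIG:
            n += 1
            if x != y:
                if (x in PURINES) == (y in PURINES):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        return "undefined", 0
    P, Q = ts / n, tv / n
    if model == "p-distance":
        return P + Q, n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return "saturated", n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q), n


def classify_columns_oracle(sequences):
    """Naive per-column site classification.

    Returns (conserved, variable, parsim_informative, singleton, excluded).
    """
    conserved = variable = informative = singleton = excluded = 0
    length = len(sequences[0])
    for col in range(length):
        bases = [s[col] for s in sequences if s[col] in UNAMBIG]
        if len(bases) < 2:
            excluded += 1
        elif len(set(bases)) == 1:
            conserved += 1
        else:
            variable += 1
            with_two = [b for b in set(bases) if bases.count(b) >= 2]
            if len(with_two) >= 2:
                informative += 1
            else:
                singleton += 1
    return conserved, variable, informative, singleton, excluded


def midranks(values):
    """Midranks (1-based) computed by counting, not sorting tricks."""
    out = []
    for v in values:
        n_less = sum(1 for w in values if w < v)
        n_eq = sum(1 for w in values if w == v)
        out.append(n_less + (n_eq + 1) / 2.0)
    return out


def _two_sided(all_stats, observed):
    n = len(all_stats)
    lo = sum(1 for w in all_stats if w <= observed + 1e-12) / n
    hi = sum(1 for w in all_stats if w >= observed - 1e-12) / n
    return min(1.0, 2.0 * min(lo, hi))


def signed_rank_exact_oracle(a, b):
    """Two-sided exact p by full 2^n sign-flip enumeration (midranks kept fixed)."""
    d = [x - y for x, y in zip(a, b) if x != y]
    ranks = midranks([abs(x) for x in d])
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    stats = [
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in product((0, 1), repeat=len(d))
    ]
    return _two_sided(stats, w_obs)


def rank_sum_exact_oracle(a, b):
    """Two-sided exact p by enumerating all C(n+m, n) group assignments."""
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    n_a = len(a)
    w_obs = sum(ranks[:n_a])
    stats = [
        sum(ranks[i] for i in idx)
        for idx in combinations(range(len(pooled)), n_a)
    ]
    return _two_sided(stats, w_obs)


def divergence_metrics_oracle(labels, species, matrix):
    """The six divergence metrics recomputed naively from a square matrix.

    Returns dict metric -> list of raw values (empty list = missing metric).
    """
    n = len(labels)
    intra, inter = [], []
    by_sp_intra, by_sp_hetero = {}, {}
    for i in range(n):
        for j in range(i + 1, n):
            d = matrix[i][j]
            if d != d:  # NaN
                continue
            if species[i] == species[j]:
                intra.append(d)
                by_sp_intra.setdefault(species[i], []).append(d)
            else:
                inter.append(d)
                by_sp_hetero.setdefault(species[i], []).append(d)
                by_sp_hetero.setdefault(species[j], []).append(d)
    return {
        "all_intra": intra,
        "mean_theta": [sum(v) / len(v) for _, v in sorted(by_sp_intra.items())],
        "coalescent_depth": [max(v) for _, v in sorted(by_sp_intra.items())],
        "all_inter": inter,
        "theta_prime": [sum(v) / len(v) for _, v in sorted(by_sp_hetero.items())],
        "min_inter": [min(v) for _, v in sorted(by_sp_hetero.items())],
    }
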