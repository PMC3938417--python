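"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain, slow enumeration — explicit loops
over pairs, sites and partitions, exact rational arithmetic for the Ewens
distribution — deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

MISSING = 255
GAP = 4


def pair_diff(a, b) -> int:
    """Differences between two coded sequences over comparable sites."""
    d = 0
    for x, y in zip(a, b):
        if x in (MISSING, GAP) or y in (MISSING, GAP):
            continue
        if x != y:
            d += 1
    return d


def mean_pairwise(matrix) -> float:
    rows = [list(r) for r in np.asarray(matrix, dtype=int)]
    diffs = [pair_diff(a, b) for a, b in combinations(rows, 2)]
    return sum(diffs) / len(diffs)


def seg_sites(matrix) -> int:
    m = np.asarray(matrix, dtype=int)
    s = 0
    for j in range(m.shape[1]):
        states = {int(v) for v in m[:, j] if v not in (MISSING, GAP)}
        if len(states) > 1:
            s += 1
    return s


def singletons_per_seq(matrix) -> list[int]:
    m = np.asarray(matrix, dtype=int)
    n = m.shape[0]
    u = [0] * n
    for j in range(m.shape[1]):
        col = [(i, int(v)) for i, v in enumerate(m[:, j]) if v not in (MISSING, GAP)]
        states: dict[int, list[int]] = {}
        for i, v in col:
            states.setdefault(v, []).append(i)
        if len(states) == 2:
            sizes = sorted(states.items(), key=lambda kv: len(kv[1]))
            if len(sizes[0][1]) == 1:
                u[sizes[0][1][0]] += 1
    return u


def n_haplotypes(matrix) -> int:
    return len({tuple(int(v) for v in row) for row in np.asarray(matrix, dtype=int)})


def tajimas_d(matrix) -> float | None:
    m = np.asarray(matrix, dtype=int)
    n = m.shape[0]
    s = seg_sites(m)
    if s == 0:
        return None
    kbar = mean_pairwise(m)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (kbar - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def stirling_unsigned(n: int, k: int) -> int:
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0:
        return 0
    return stirling_unsigned(n - 1, k - 1) + (n - 1) * stirling_unsigned(n - 1, k)


def ewens_pmf_exact(n: int, theta: Fraction) -> list[Fraction]:
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    return [
        stirling_unsigned(n, k) * theta**k / rising for k in range(1, n + 1)
    ]


def fus_fs(matrix) -> float | None:
    m = np.asarray(matrix, dtype=int)
    n = m.shape[0]
    kbar = mean_pairwise(m)
    k_obs = n_haplotypes(m)
    if k_obs <= 1 or kbar <= 0:
        return None
    theta = Fraction(kbar).limit_denominator(10**12)
    pmf = ewens_pmf_exact(n, theta)
    sp = sum(pmf[k_obs - 1 :])
    if sp >= 1:
        return None
    return math.log(float(sp) / float(1 - sp))


def r2(matrix) -> float | None:
    m = np.asarray(matrix, dtype=int)
    n = m.shape[0]
    s = seg_sites(m)
    if s == 0:
        return None
    kbar = mean_pairwise(m)
    u = singletons_per_seq(m)
    total = sum((ui - kbar / 2.0) ** 2 for ui in u)
    return math.sqrt(total / n) / s


def mismatch_freqs(matrix) -> list[float]:
    rows = [list(r) for r in np.asarray(matrix, dtype=int)]
    diffs = [pair_diff(a, b) for a, b in combinations(rows, 2)]
    out = [0.0] * (max(diffs) + 1)
    for d in diffs:
        out[d] += 1
    return [x / len(diffs) for x in out]


def haplotype_diversity_pairs(counts) -> float:
    """Probability two draws without replacement differ, by enumeration."""
    labels = []
    for idx, c in enumerate(counts):
        labels.extend([idx] * int(c))
    pairs = list(combinations(range(len(labels)), 2))
    differing = sum(1 for i, j in pairs if labels[i] != labels[j])
    return differing / len(pairs)
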