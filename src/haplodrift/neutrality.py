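"""Neutrality tests: Tajima's D, Fu's Fs and Ramos-Onsins & Rozas's R2.

Each statistic is computed from an alignment (or a binary derived-state
matrix from the coalescent engine) and tested against a null distribution
from standard-neutral coalescent simulations conditioned on the observed
number of segregating sites (fixed-S), the convention of DnaSP.  Tajima's
D is two-tailed; Fs and R2 are one-tailed on the low side, where their
demographic-expansion signal lies.

Fu's Fs uses the Ewens sampling formula: with theta estimated by the mean
pairwise difference k_bar,

    P(K = k) = |s(n, k)| theta^k / theta^(n),

where |s(n, k)| are unsigned Stirling numbers of the first kind (computed
exactly in integer arithmetic, combined in log space) and theta^(n) is the
rising factorial.  S' = P(K >= k_obs) and Fs = ln(S' / (1 - S')).

Sites with missing data are handled by pairwise deletion; a "singleton"
for R2 is any site at which exactly one sequence differs from all others
(folded definition, no outgroup needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .alignment import Alignment, GAP, MISSING
from .coalescent import simulate_fixed_s
from .diversity import pairwise_differences

__all__ = [
    "NeutralityResult",
    "segregating_sites",
    "mean_pairwise_differences",
    "singleton_counts",
    "distinct_haplotype_count",
    "tajimas_d_statistic",
    "fus_fs_statistic",
    "r2_from_components",
    "site_stats",
    "coalescent_null",
    "tajimas_d",
    "fus_fs",
    "r2_statistic",
    "neutrality_tests",
    "ewens_log_pmf",
]


# ---------------------------------------------------------------------------
# site-level summaries (work on base-coded alignments and binary matrices)
# ---------------------------------------------------------------------------


def _is_binary(matrix: np.ndarray) -> bool:
    return matrix.dtype == bool


def segregating_sites(matrix: np.ndarray) -> int:
    """Number of sites with at least two observed base states."""
    if _is_binary(matrix):
        c = matrix.sum(axis=0)
        return int(np.sum((c > 0) & (c < matrix.shape[0])))
    s = 0
    for col in matrix.T:
        obs = col[(col != MISSING) & (col != GAP)]
        if obs.size and np.unique(obs).size > 1:
            s += 1
    return s


def mean_pairwise_differences(matrix: np.ndarray) -> float:
    """Mean number of pairwise differences k_bar (pairwise deletion)."""
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if _is_binary(matrix):
        c = matrix.sum(axis=0).astype(float)
        return float(np.sum(c * (n - c)) * 2.0 / (n * (n - 1)))
    k, _ = pairwise_differences(matrix)
    return float(np.mean(k))


def singleton_counts(matrix: np.ndarray) -> np.ndarray:
    """Per-sequence count of singleton sites (folded definition).

    A singleton site has exactly two observed states with the minority
    carried by exactly one sequence; that sequence gets the singleton.
    """
    n = matrix.shape[0]
    u = np.zeros(n, dtype=int)
    if _is_binary(matrix):
        c = matrix.sum(axis=0)
        for j in np.where(c == 1)[0]:
            u[np.argmax(matrix[:, j])] += 1
        for j in np.where(c == n - 1)[0]:
            u[np.argmin(matrix[:, j])] += 1
        return u
    for col in matrix.T:
        keep = (col != MISSING) & (col != GAP)
        obs = col[keep]
        vals, counts = np.unique(obs, return_counts=True)
        if vals.size == 2 and counts.min() == 1 and obs.size >= 2:
            minority = vals[np.argmin(counts)]
            carrier = np.where(keep)[0][obs == minority][0]
            u[carrier] += 1
    return u


def distinct_haplotype_count(matrix: np.ndarray) -> int:
    """Number of distinct sequences (exact identity over all sites)."""
    return len({row.tobytes() for row in np.ascontiguousarray(matrix)})


# ---------------------------------------------------------------------------
# statistics from summaries
# ---------------------------------------------------------------------------


def tajimas_d_statistic(n: int, s: int, k_bar: float) -> float | None:
    """Tajima's D from sample size, segregating sites and k_bar.

    Returns None when S = 0 (the test is undefined).
    """
    if s == 0:
        return None
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((k_bar - s / a1) / math.sqrt(var))


@lru_cache(maxsize=None)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)|, k = 0..n."""
    if n == 0:
        return (1,)
    prev = _stirling_row(n - 1)
    row = [0] * (n + 1)
    for k in range(1, n + 1):
        row[k] = prev[k - 1] + (n - 1) * (prev[k] if k <= n - 1 else 0)
    return tuple(row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling formula."""
    if n < 1:
        raise ValueError("n must be positive")
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = _stirling_row(n)
    log_s = np.array([math.log(row[k]) for k in range(1, n + 1)])
    ks = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    logp = log_s + ks * math.log(theta) - log_rising
    # exact normalisation guards against float error in huge Stirling rows
    return logp - logsumexp(logp)


def fus_fs_statistic(n: int, k_obs: int, k_bar: float) -> float | None:
    """Fu's Fs from sample size, observed haplotype number and k_bar.

    Returns None when the statistic is undefined (k_obs = 1 makes
    S' = 1; k_bar = 0 leaves theta undefined).
    """
    if k_obs <= 1 or k_bar <= 0:
        return None
    logp = ewens_log_pmf(n, k_bar)
    log_sp = logsumexp(logp[k_obs - 1 :])  # P(K >= k_obs)
    if log_sp >= 0.0:
        return None  # S' = 1 to machine precision
    log_one_minus = math.log1p(-math.exp(log_sp))
    return float(log_sp - log_one_minus)


def r2_from_components(n: int, s: int, k_bar: float, u: np.ndarray) -> float | None:
    """Ramos-Onsins & Rozas's R2 from singleton counts.

    R2 = sqrt( (1/n) * sum_i (U_i - k_bar/2)^2 ) / S; None when S = 0.
    """
    if s == 0:
        return None
    dev = np.asarray(u, dtype=float) - k_bar / 2.0
    return float(math.sqrt(np.mean(dev**2)) / s)


@dataclass
class SiteStats:
    n: int
    s: int
    k_bar: float
    k_obs: int
    u: np.ndarray


def site_stats(matrix: np.ndarray) -> SiteStats:
    """All site-level summaries needed by the three tests."""
    return SiteStats(
        n=matrix.shape[0],
        s=segregating_sites(matrix),
        k_bar=mean_pairwise_differences(matrix),
        k_obs=distinct_haplotype_count(matrix),
        u=singleton_counts(matrix),
    )


# ---------------------------------------------------------------------------
# coalescent null distributions and p-values
# ---------------------------------------------------------------------------


def coalescent_null(
    n: int,
    s_obs: int,
    reps: int = 1000,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Null distributions of (D, Fs, R2) under the standard coalescent.

    Every replicate is a Kingman genealogy with exactly ``s_obs``
    mutations placed uniformly on the branches (fixed-S conditioning).
    Returns arrays of the three statistics (NaN where undefined).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if s_obs < 1:
        raise ValueError("fixed-S conditioning needs s_obs >= 1")
    rng = np.random.default_rng(seed)
    out = {"D": np.empty(reps), "Fs": np.empty(reps), "R2": np.empty(reps)}
    for r in range(reps):
        m = simulate_fixed_s(n, s_obs, rng)
        st = site_stats(m)
        d = tajimas_d_statistic(st.n, st.s, st.k_bar)
        fs = fus_fs_statistic(st.n, st.k_obs, st.k_bar)
        r2 = r2_from_components(st.n, st.s, st.k_bar, st.u)
        out["D"][r] = np.nan if d is None else d
        out["Fs"][r] = np.nan if fs is None else fs
        out["R2"][r] = np.nan if r2 is None else r2
    return out


def _p_two_tailed(null: np.ndarray, obs: float) -> float:
    null = null[~np.isnan(null)]
    lo = np.mean(null <= obs + 1e-12)
    hi = np.mean(null >= obs - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _p_low_tail(null: np.ndarray, obs: float) -> float:
    null = null[~np.isnan(null)]
    return float(np.mean(null <= obs + 1e-12))


def _population_matrix(aln: Alignment, population: str | None) -> np.ndarray:
    m = aln.population_matrix(population)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    return m


def tajimas_d(
    aln: Alignment,
    population: str | None = None,
    reps: int = 1000,
    seed: int | None = None,
    null: dict[str, np.ndarray] | None = None,
) -> tuple[float | None, float | None]:
    """Tajima's D with a two-tailed coalescent p-value.

    Returns (None, None) when no site segregates.
    """
    st = site_stats(_population_matrix(aln, population))
    d = tajimas_d_statistic(st.n, st.s, st.k_bar)
    if d is None:
        return None, None
    if null is None:
        null = coalescent_null(st.n, st.s, reps, seed)
    return d, _p_two_tailed(null["D"], d)


def fus_fs(
    aln: Alignment,
    population: str | None = None,
    reps: int = 1000,
    seed: int | None = None,
    null: dict[str, np.ndarray] | None = None,
) -> tuple[float | None, float | None]:
    """Fu's Fs with a one-tailed (low) coalescent p-value."""
    m = _population_matrix(aln, population)
    st = site_stats(m)
    fs = fus_fs_statistic(st.n, st.k_obs, st.k_bar)
    if fs is None:
        return None, None
    if null is None:
        null = coalescent_null(st.n, st.s, reps, seed)
    return fs, _p_low_tail(null["Fs"], fs)


def r2_statistic(
    aln: Alignment,
    population: str | None = None,
    reps: int = 1000,
    seed: int | None = None,
    null: dict[str, np.ndarray] | None = None,
) -> tuple[float | None, float | None]:
    """R2 with a one-tailed (low) coalescent p-value."""
    st = site_stats(_population_matrix(aln, population))
    r2 = r2_from_components(st.n, st.s, st.k_bar, st.u)
    if r2 is None:
        return None, None
    if null is None:
        null = coalescent_null(st.n, st.s, reps, seed)
    return r2, _p_low_tail(null["R2"], r2)


@dataclass
class NeutralityResult:
    """All neutrality-test outputs for one population sample."""

    population: str | None
    n: int
    S: int
    k_bar: float
    D: float | None
    Fs: float | None
    R2: float | None
    p_D: float | None
    p_Fs: float | None
    p_R2: float | None

    def as_dict(self) -> dict:
        return {
            "population": self.population,
            "n": self.n,
            "S": self.S,
            "k_bar": self.k_bar,
            "D": self.D,
            "Fs": self.Fs,
            "R2": self.R2,
            "p_D": self.p_D,
            "p_Fs": self.p_Fs,
            "p_R2": self.p_R2,
        }


def neutrality_tests(
    aln: Alignment,
    population: str | None = None,
    reps: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """Run D, Fs and R2 against one shared fixed-S coalescent null."""
    m = _population_matrix(aln, population)
    st = site_stats(m)
    d = tajimas_d_statistic(st.n, st.s, st.k_bar) if st.n >= 4 else None
    fs = fus_fs_statistic(st.n, st.k_obs, st.k_bar)
    r2 = r2_from_components(st.n, st.s, st.k_bar, st.u)
    null = coalescent_null(st.n, st.s, reps, seed) if st.s >= 1 else None
    return NeutralityResult(
        population=population,
        n=st.n,
        S=st.s,
        k_bar=st.k_bar,
        D=d,
        Fs=fs,
        R2=r2,
        p_D=None if (d is None or null is None) else _p_two_tailed(null["D"], d),
        p_Fs=None if (fs is None or null is None) else _p_low_tail(null["Fs"], fs),
        p_R2=None if (r2 is None or null is None) else _p_low_tail(null["R2"], r2),
    )
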