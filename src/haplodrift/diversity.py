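"""Diversity statistics on haplotype tables and alignments.

Implements the per-population summary columns of the study's diversity
table: haplotype number h, private haplotypes P-h, Nei's unbiased
haplotype diversity h.d., and nucleotide diversity pi (reported x 10^-3),
plus a haplotype-frequency Fst with a permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, MISSING, GAP
from .tables import HaplotypeTable

__all__ = [
    "DiversitySummary",
    "haplotype_diversity",
    "haplotype_summary",
    "nucleotide_diversity",
    "pairwise_differences",
    "fst_haplotype",
    "summarize_populations",
]


@dataclass
class DiversitySummary:
    """One row of a diversity summary table."""

    population: str
    n: int
    h: int
    private_h: int | None
    hap_diversity: float | None
    nuc_diversity: float | None  # per site; multiply by 1e3 for reporting

    def __post_init__(self) -> None:
        if self.h > self.n:
            raise ValueError("haplotype number cannot exceed sample size")


def haplotype_diversity(counts) -> float | None:
    """Nei's unbiased haplotype (gene) diversity.

    H = n/(n-1) * (1 - sum p_i^2): the probability that two individuals
    drawn without replacement carry different haplotypes.  Returns None
    (printed as "-") when n < 2.
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        return None
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def haplotype_summary(table: HaplotypeTable, population: str) -> tuple[int, int]:
    """Haplotype number h and private haplotypes P-h for one population.

    A haplotype is private when it is absent from every *other* population
    at the same grouping level (country vs. country, continent vs.
    continent).  Aggregate rows ("All") and the inbred-strains column are
    never part of the comparison set for wild populations.
    """
    table._check_pop(population)
    col = table.counts[population]
    h = int((col > 0).sum())

    level = table.level_of(population)
    others = [
        p
        for p in table.populations
        if p != population
        and table.level_of(p) == level
        and table.level_of(p) not in ("strains", "all")
    ]
    if level in ("strains", "all"):
        # strains/aggregate rows are compared against wild populations at
        # the continent level (the broadest wild grouping available)
        others = [p for p in table.populations if table.level_of(p) == "continent"]
    if not others:
        return h, h
    present_elsewhere = (table.counts[others] > 0).any(axis=1)
    private = int(((col > 0) & ~present_elsewhere).sum())
    return h, private


def pairwise_differences(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs difference counts and comparable-site counts.

    Differences are counted over sites where both sequences are observed
    (non-missing) and neither is a gap.  Returns two vectors of length
    n(n-1)/2 in (i, j), i < j order: raw difference counts and the number
    of comparable sites per pair.
    """
    m = np.asarray(matrix)
    n = m.shape[0]
    usable = (m != MISSING) & (m != GAP)
    iu, ju = np.triu_indices(n, k=1)
    both = usable[iu] & usable[ju]
    diff = (m[iu] != m[ju]) & both
    return diff.sum(axis=1), both.sum(axis=1)


def nucleotide_diversity(
    aln: Alignment,
    population: str | None = None,
    *,
    deletion: str = "pairwise",
) -> float | None:
    """Nucleotide diversity pi: mean pairwise differences per site.

    pi = [2 / (n(n-1))] * sum_{i<j} k_ij / L_ij with k_ij counted over
    mutually observed non-gap sites.  ``deletion="pairwise"`` (default)
    uses the per-pair comparable length L_ij, matching data sets that pool
    partial published sequences; ``deletion="complete"`` restricts every
    pair to the sites observed in *all* sequences.  Returns None when
    n < 2.
    """
    m = aln.population_matrix(population)
    if m.shape[0] < 2:
        return None
    if deletion == "complete":
        keep = ((m != MISSING) & (m != GAP)).all(axis=0)
        m = m[:, keep]
        if m.shape[1] == 0:
            raise ValueError("no site observed in all sequences")
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion policy: {deletion!r}")
    k, L = pairwise_differences(m)
    if (L == 0).any():
        raise ValueError("a sequence pair shares no observed site")
    return float(np.mean(k / L))


def _gene_diversity_unbiased(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    return n / (n - 1.0) * (1.0 - np.sum(p**2))


def fst_haplotype(
    table: HaplotypeTable,
    pop_a: str,
    pop_b: str,
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Haplotype-frequency Fst between two populations with permutation p.

    Fst = (H_T - H_S) / H_T where H is Nei's unbiased gene diversity, H_T
    is computed on the pooled sample and H_S is the sample-size-weighted
    mean within-population diversity.  The p-value is the fraction of
    label permutations with Fst at least as large as observed.  When both
    populations are fixed for the same haplotype (H_T = 0) Fst is defined
    as 0 with p = 1.
    """
    ca = table.counts[pop_a].to_numpy(dtype=float) if pop_a in table.counts else None
    if ca is None:
        raise KeyError(f"unknown population: {pop_a!r}")
    table._check_pop(pop_b)
    cb = table.counts[pop_b].to_numpy(dtype=float)
    na, nb = ca.sum(), cb.sum()
    if na < 2 or nb < 2:
        raise ValueError("both populations need n >= 2 for Fst")

    def fst_from_counts(a: np.ndarray, b: np.ndarray) -> float | None:
        ht = _gene_diversity_unbiased(a + b)
        if ht == 0.0:
            return None
        hs = (a.sum() * _gene_diversity_unbiased(a) + b.sum() * _gene_diversity_unbiased(b)) / (
            a.sum() + b.sum()
        )
        return min(1.0, max(0.0, (ht - hs) / ht))

    obs = fst_from_counts(ca, cb)
    if obs is None:
        return 0.0, 1.0

    # permute individuals between the two populations
    rng = np.random.default_rng(seed)
    pooled = np.repeat(np.arange(len(ca)), (ca + cb).astype(int))
    n_hap = len(ca)
    hits = 0
    for _ in range(permutations):
        rng.shuffle(pooled)
        a = np.bincount(pooled[: int(na)], minlength=n_hap).astype(float)
        b = np.bincount(pooled[int(na) :], minlength=n_hap).astype(float)
        f = fst_from_counts(a, b)
        if f is not None and f >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return obs, p


def summarize_populations(
    table: HaplotypeTable,
    aln: Alignment | None = None,
    level: str | None = None,
) -> pd.DataFrame:
    """Per-population diversity summary (the study's Table-3 layout).

    Frequency-based columns (n, h, P-h, h.d.) come from the count table;
    pi requires an alignment whose population labels match the table
    columns and is left NaN otherwise.  ``level`` restricts the rows
    (e.g. "country" or "continent").
    """
    rows = []
    for pop in table.populations:
        if level is not None and table.level_of(pop) != level:
            continue
        n = table.sample_size(pop)
        if n == 0:
            continue
        h, private = haplotype_summary(table, pop)
        hd = haplotype_diversity(table.counts[pop])
        pi = None
        if aln is not None and pop in aln.population_set:
            pi = nucleotide_diversity(aln, pop)
        rows.append(
            {
                "population": pop,
                "n": n,
                "h": h,
                "P-h": private,
                "h.d.": math.nan if hd is None else round(hd, 2),
                "pi_x1e3": math.nan if pi is None else round(pi * 1e3, 2),
            }
        )
    return pd.DataFrame(rows).set_index("population")
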