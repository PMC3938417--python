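"""Synthetic alignments and haplotype tables.

Every statistical stage of the package is testable without any sequence
download: this module generates haplotype count tables with a chosen
frequency spectrum (one focal haplotype at frequency i0, the rest sharing
1 - i0 equally — the founding spectrum of the forward simulations) and
alignments whose haplotype structure realises an arbitrary count table.

Haplotype reference sequences are built by placing exactly S mutations on
a genealogy over the haplotypes — a Kingman coalescent tree or a star
tree (every haplotype on its own branch, the limit of a hard expansion).
Mutations follow infinite sites on a finite length L: S distinct
positions, ancestral base uniform, derived base uniformly different.
Partial sequences are emulated by terminal truncation (random prefix or
suffix marked missing), mimicking partially published records rather than
random internal gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, MISSING
from .coalescent import sample_genealogy
from .tables import HaplotypeTable

__all__ = ["SyntheticSpec", "generate_table", "generate_alignment"]


def generate_table(
    n_haplotypes: int,
    n_samples: int,
    i0: float,
    seed: int | None = None,
    prefix: str = "H",
    population: str = "pop1",
) -> HaplotypeTable:
    """A one-population table with a focal-haplotype frequency spectrum.

    Counts realise (i0, (1-i0)/(K-1), ...) by largest-remainder rounding
    to ``n_samples``; ties go to the earlier haplotype, so the result is
    deterministic (``seed`` is accepted for API symmetry only).
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if not (0.0 < i0 <= 1.0):
        raise ValueError("i0 must be in (0, 1]")
    if n_haplotypes > 1 and i0 < 1.0 / n_samples:
        raise ValueError(
            f"i0={i0} would round the focal haplotype to zero at n={n_samples}"
        )
    from .forward_sim import initial_haplotype_counts

    counts = initial_haplotype_counts(n_haplotypes, n_samples, i0)
    names = [f"{prefix}{i + 1}" for i in range(n_haplotypes)]
    keep = counts > 0
    frame = pd.DataFrame(
        {population: counts[keep]}, index=np.array(names)[keep]
    )
    return HaplotypeTable(frame)


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic alignment.

    ``table`` fixes the haplotype frequency spectrum per population; L is
    the alignment length (664 for D-loop-like, 549 for cyt-b-like data);
    S segregating sites are placed on the chosen genealogy over the
    haplotypes; ``missing_fraction`` of samples are truncated to partial
    records.
    """

    table: HaplotypeTable
    L: int = 664
    S: int = 30
    genealogy: str = "coalescent"
    missing_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S > self.L:
            raise ValueError("cannot place more segregating sites than sites")
        if self.S < 0 or self.L < 1:
            raise ValueError("S and L must be non-negative / positive")
        if self.genealogy not in ("coalescent", "star"):
            raise ValueError("genealogy must be 'coalescent' or 'star'")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")


def _haplotype_signatures(
    k: int, s: int, genealogy: str, rng: np.random.Generator
) -> np.ndarray:
    """Binary (k, s) derived-state signatures, distinct across haplotypes.

    Star genealogy: every mutation sits on one haplotype's own branch;
    the first k-1 mutations are dealt to haplotypes 1..k-1 so that all
    signatures differ.  Coalescent genealogy: mutations fall on a Kingman
    tree over the k haplotype lineages; placement is redrawn (bounded)
    until all signatures are distinct.
    """
    if k == 1:
        return np.zeros((1, s), dtype=bool)
    if s < k - 1:
        raise ValueError(
            f"S={s} segregating sites cannot distinguish {k} haplotypes"
        )
    if genealogy == "star":
        sig = np.zeros((k, s), dtype=bool)
        owners = np.concatenate(
            [np.arange(1, k), rng.integers(0, k, size=s - (k - 1))]
        )
        sig[owners, np.arange(s)] = True
        return sig
    for _ in range(200):
        gen = sample_genealogy(k, rng)
        lengths = gen.branch_lengths()
        branches = rng.choice(len(lengths), size=s, p=lengths / lengths.sum())
        sig = gen.tip_sets()[branches].T.copy()
        if len({row.tobytes() for row in sig}) == k:
            return sig
    raise RuntimeError(
        f"could not realise {k} distinct haplotypes with S={s} on a "
        "coalescent genealogy; increase S"
    )


def generate_alignment(spec: SyntheticSpec) -> Alignment:
    """Emit an alignment whose collapse reproduces ``spec.table``.

    Deterministic for a fixed seed (byte-identical output).  Samples are
    emitted grouped by haplotype in table order, so collapsing a
    missing-free alignment recovers the table's counts haplotype by
    haplotype.
    """
    rng = np.random.default_rng(spec.seed)
    table = spec.table
    k = len(table.haplotype_ids)

    signatures = _haplotype_signatures(k, spec.S, spec.genealogy, rng)

    # infinite sites on finite L: distinct positions, uniform bases
    sites = rng.choice(spec.L, size=spec.S, replace=False)
    ancestral = rng.integers(0, 4, size=spec.L).astype(np.uint8)
    derived = (ancestral[sites] + rng.integers(1, 4, size=spec.S)) % 4

    refs = np.tile(ancestral, (k, 1))
    for j, site in enumerate(sites):
        refs[signatures[:, j], site] = derived[j]

    sample_ids: list[str] = []
    populations: list[str] = []
    rows: list[np.ndarray] = []
    counter = 1
    for pop in table.populations:
        col = table.counts[pop]
        for h_idx, hap in enumerate(table.haplotype_ids):
            for _ in range(int(col[hap])):
                sample_ids.append(f"s{counter:05d}")
                populations.append(pop)
                rows.append(refs[h_idx].copy())
                counter += 1
    matrix = np.stack(rows)

    if spec.missing_fraction > 0.0:
        n = matrix.shape[0]
        n_partial = int(round(spec.missing_fraction * n))
        chosen = rng.choice(n, size=n_partial, replace=False)
        for i in chosen:
            keep_len = int(rng.integers(max(1, int(0.4 * spec.L)), spec.L))
            if rng.random() < 0.5:  # keep a prefix
                matrix[i, keep_len:] = MISSING
            else:  # keep a suffix
                matrix[i, : spec.L - keep_len] = MISSING

    return Alignment(sample_ids, populations, matrix)
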