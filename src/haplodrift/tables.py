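"""Haplotype count tables.

A :class:`HaplotypeTable` holds non-negative integer counts keyed
haplotype x population.  The two packaged tables ship the printed
occurrence counts of mtDNA cytochrome-b haplotypes (C1-C39, 549 bp) and
D-loop haplotypes (D1-D25, 664 bp) of wild Norway rats from four
continents plus a set of inbred laboratory strains.  Those tables are the
substrate for all frequency-based statistics in :mod:`haplodrift.diversity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeTable",
    "load_printed_table",
    "read_table_csv",
    "write_table_csv",
    "POPULATION_LEVELS",
]

#: Grouping level of every row of the packaged tables.  Continent rows are
#: the sums of their country rows; "All" additionally includes the inbred
#: strains.  Private-haplotype comparisons are made within one level and
#: never against the strains or aggregate rows.
POPULATION_LEVELS: dict[str, str] = {
    "Europe": "continent",
    "Asia": "continent",
    "Africa": "continent",
    "North America": "continent",
    "French Polynesia": "continent",
    "Denmark": "country",
    "France": "country",
    "Germany": "country",
    "Sweden": "country",
    "Cambodia": "country",
    "China": "country",
    "Indonesia": "country",
    "Japan": "country",
    "Thailand": "country",
    "Vietnam": "country",
    "South Africa": "country",
    "Egypt": "country",
    "USA": "country",
    "Society Islands": "country",
    "Tubai": "country",
    "Inbred strains": "strains",
    "All": "all",
}

_FIXTURES = {"cytb": "cytb_haplotypes.csv", "dloop": "dloop_haplotypes.csv"}


@dataclass
class HaplotypeTable:
    """Integer haplotype counts per population.

    Parameters
    ----------
    counts
        DataFrame indexed by haplotype id with one integer column per
        population.
    levels
        Optional population -> grouping-level map ("country", "continent",
        "strains", "all").  Populations without an entry are treated as
        one flat level.
    """

    counts: pd.DataFrame
    levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("duplicate haplotype ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate population names")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("haplotype counts must be integers")
            counts = counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("haplotype counts must be non-negative")
        if (counts.sum(axis=1) < 1).any():
            bad = counts.index[counts.sum(axis=1) < 1].tolist()
            raise ValueError(f"haplotypes with zero total count: {bad}")
        self.counts = counts

    # -- basic accessors -------------------------------------------------

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    def sample_size(self, population: str) -> int:
        """Total samples in one population column."""
        self._check_pop(population)
        return int(self.counts[population].sum())

    def population_counts(self, population: str) -> pd.Series:
        """Non-zero haplotype counts of one population."""
        self._check_pop(population)
        col = self.counts[population]
        return col[col > 0]

    def frequencies(self, population: str) -> pd.Series:
        """Relative haplotype frequencies of one population."""
        n = self.sample_size(population)
        if n == 0:
            raise ValueError(f"population {population!r} has no samples")
        return self.counts[population] / n

    def level_of(self, population: str) -> str:
        return self.levels.get(population, "population")

    def _check_pop(self, population: str) -> None:
        if population not in self.counts.columns:
            raise KeyError(f"unknown population: {population!r}")

    def subset(self, populations: list[str]) -> "HaplotypeTable":
        """Restrict to some populations, dropping unobserved haplotypes."""
        for p in populations:
            self._check_pop(p)
        sub = self.counts[populations]
        sub = sub[sub.sum(axis=1) > 0]
        levels = {p: self.levels[p] for p in populations if p in self.levels}
        return HaplotypeTable(sub, levels)


def load_printed_table(name: str) -> HaplotypeTable:
    """Load one of the two packaged haplotype count tables.

    ``name`` is ``"cytb"`` (C1-C39, 161 samples incl. 5 inbred strains) or
    ``"dloop"`` (D1-D25, 239 samples incl. 27 inbred strains).  Rows and
    counts are exactly as printed, including continent aggregate rows, the
    inbred-strains row and the grand-total "All" column.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown table {name!r}; expected 'cytb' or 'dloop'")
    ref = resources.files("haplodrift.data").joinpath(_FIXTURES[name])
    with ref.open("r") as fh:
        counts = pd.read_csv(fh, index_col="haplotype_id")
    return HaplotypeTable(counts, dict(POPULATION_LEVELS))


def read_table_csv(path) -> HaplotypeTable:
    """Read a haplotype table from CSV (first column haplotype_id)."""
    counts = pd.read_csv(path, index_col=0)
    counts.index = counts.index.astype(str)
    return HaplotypeTable(counts)


def write_table_csv(table: HaplotypeTable, path) -> None:
    table.counts.to_csv(path, index_label="haplotype_id")
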