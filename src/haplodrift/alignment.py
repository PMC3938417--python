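"""Aligned mtDNA sequences and haplotype collapsing.

Sequences are pre-aligned reads over ``{A, C, G, T, -, N, ?}``.  ``N`` and
``?`` are missing data; ``-`` (alignment gap) is kept as a fifth character
state for haplotype identity but never counted as a pairwise difference.
Published D-loop records range from 278 to the full 664 bp, so partial
sequences are first-class citizens: they are padded with ``?`` to the
declared alignment length and later assigned to haplotypes by the minimal
Hamming distance over their observed sites (the "minimal distance rule").

Sites are 0-based internally and 1-based in user-facing messages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "HaplotypeAssignment",
    "read_alignment",
    "read_labels",
    "collapse_haplotypes",
    "write_fasta",
    "MISSING",
    "GAP",
]

# byte codes for the 4 bases, the gap state and missing data
_ALPHABET = "ACGT-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
GAP = _CODE["-"]
MISSING = 255
_DECODE = {**{i: c for c, i in _CODE.items()}, MISSING: "?"}


def encode_sequence(seq: str, sample_id: str = "?") -> np.ndarray:
    """Encode one upper-cased sequence string to byte codes.

    Raises a ValueError naming the (1-based) site and record on any
    character outside ``{A,C,G,T,-,N,?}``.
    """
    out = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq.upper()):
        if c in _CODE:
            out[i] = _CODE[c]
        elif c in ("N", "?"):
            out[i] = MISSING
        else:
            raise ValueError(
                f"illegal character {c!r} at site {i + 1} of record {sample_id!r}"
            )
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_DECODE[int(c)] for c in codes)


@dataclass
class Alignment:
    """A fixed-length alignment of labelled samples.

    ``matrix`` is (n_samples, L) uint8 with :data:`MISSING` marking sites
    not covered by a record.
    """

    sample_ids: list[str]
    populations: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise ValueError("empty alignment")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("one population label per sample required")
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape does not match sample count")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def population_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_matrix(self, population: str | None) -> np.ndarray:
        """Rows of one population (or all rows when ``population`` is None)."""
        if population is None:
            return self.matrix
        mask = np.array([p == population for p in self.populations])
        if not mask.any():
            raise KeyError(f"unknown population: {population!r}")
        return self.matrix[mask]

    def sequences(self) -> list[str]:
        return [decode_sequence(row) for row in self.matrix]


@dataclass
class HaplotypeAssignment:
    """Sample -> haplotype map produced by :func:`collapse_haplotypes`."""

    assignment: dict[str, str]
    used_missing_rule: dict[str, bool] = field(default_factory=dict)
    ties: int = 0


def read_labels(labels_path) -> tuple[dict[str, str], dict[str, int]]:
    """Read the sample table: CSV with header ``sample_id,population``.

    An optional third column ``offset`` gives the 0-based alignment start
    of a partial record (default 0).
    """
    populations: dict[str, str] = {}
    offsets: dict[str, int] = {}
    with open(labels_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError("labels file needs a header with a sample_id column")
        if "population" not in reader.fieldnames:
            raise ValueError("labels file needs a population column")
        for row in reader:
            sid = row["sample_id"].strip()
            if sid in populations:
                raise ValueError(f"duplicate sample id in labels: {sid!r}")
            populations[sid] = row["population"].strip()
            offsets[sid] = int(row.get("offset") or 0)
    return populations, offsets


def read_alignment(fasta_path, labels_path, length: int | None = None) -> Alignment:
    """Read a FASTA alignment plus its sample-to-population table.

    Records shorter than the declared alignment length are padded with
    ``?`` (missing) outside ``[offset, offset + len)``.  When ``length``
    is omitted the longest record (plus offset) defines L.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {fasta_path}")
    populations, offsets = read_labels(labels_path)

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids in FASTA: {dupes}")
    for sid in ids:
        if sid not in populations:
            raise ValueError(f"sample {sid!r} has no row in the labels file")

    if length is None:
        length = max(len(r.seq) + offsets.get(r.id, 0) for r in records)

    matrix = np.full((len(records), length), MISSING, dtype=np.uint8)
    for i, rec in enumerate(records):
        codes = encode_sequence(str(rec.seq), rec.id)
        off = offsets.get(rec.id, 0)
        if off < 0 or off + len(codes) > length:
            raise ValueError(
                f"record {rec.id!r} (length {len(codes)}, offset {off}) "
                f"does not fit the declared alignment length {length}"
            )
        matrix[i, off : off + len(codes)] = codes

    return Alignment(ids, [populations[s] for s in ids], matrix)


def write_fasta(aln: Alignment, fasta_path, labels_path=None) -> None:
    """Write an alignment back to FASTA (and optionally its label table)."""
    with open(fasta_path, "w") as fh:
        for sid, row in zip(aln.sample_ids, aln.matrix):
            fh.write(f">{sid}\n{decode_sequence(row)}\n")
    if labels_path is not None:
        with open(labels_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "population"])
            for sid, pop in zip(aln.sample_ids, aln.populations):
                writer.writerow([sid, pop])


def _distance_over_observed(seq: np.ndarray, refs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hamming distance of ``seq`` to each reference over sites observed
    in both, and the number of comparable sites per reference."""
    obs = seq != MISSING
    ref_obs = refs != MISSING
    both = obs[None, :] & ref_obs
    diff = (refs != seq[None, :]) & both
    return diff.sum(axis=1), both.sum(axis=1)


def collapse_haplotypes(
    aln: Alignment, prefix: str = "H"
) -> tuple["HaplotypeTable", HaplotypeAssignment]:
    """Collapse aligned sequences into haplotypes.

    Full-length (no missing data) sequences partition by exact identity
    over all sites (gaps are a fifth state).  A sequence with missing
    sites is assigned, in input order, to the existing haplotype with
    minimal Hamming distance over its observed sites; a new haplotype is
    created when that minimal distance is positive (or no haplotype exists
    yet).  Ties at distance zero (or equal positive distance) go to the
    haplotype with the highest current count, then to the earliest-created
    one; the number of tied decisions is reported.

    Returns the resulting count table and the per-sample assignment.
    """
    from .tables import HaplotypeTable  # local import to avoid a cycle
    import pandas as pd

    n = aln.n
    complete = ~(aln.matrix == MISSING).any(axis=1)
    if not complete.any() and (aln.matrix == MISSING).all(axis=1).any():
        bad = [aln.sample_ids[i] for i in np.where((aln.matrix == MISSING).all(axis=1))[0]]
        raise ValueError(f"all-missing sequences cannot be assigned: {bad}")

    hap_refs: list[np.ndarray] = []
    hap_names: list[str] = []
    hap_totals: list[int] = []
    assignment: dict[str, str] = {}
    used_rule: dict[str, bool] = {}
    ties = 0

    def new_haplotype(row: np.ndarray) -> int:
        hap_refs.append(row.copy())
        hap_names.append(f"{prefix}{len(hap_refs)}")
        hap_totals.append(0)
        return len(hap_refs) - 1

    # pass 1: complete sequences, exact identity
    key_to_idx: dict[bytes, int] = {}
    for i in np.where(complete)[0]:
        row = aln.matrix[i]
        key = row.tobytes()
        idx = key_to_idx.get(key)
        if idx is None:
            idx = new_haplotype(row)
            key_to_idx[key] = idx
        assignment[aln.sample_ids[i]] = hap_names[idx]
        used_rule[aln.sample_ids[i]] = False
        hap_totals[idx] += 1

    # pass 2: partial sequences, minimal distance rule in input order
    for i in np.where(~complete)[0]:
        row = aln.matrix[i]
        if (row == MISSING).all():
            raise ValueError(
                f"sample {aln.sample_ids[i]!r} has no observed sites"
            )
        if hap_refs:
            dists, _ = _distance_over_observed(row, np.stack(hap_refs))
            dmin = int(dists.min())
            candidates = np.where(dists == dmin)[0]
        else:
            dmin, candidates = 1, np.array([], dtype=int)

        if len(hap_refs) == 0 or dmin > 0:
            idx = new_haplotype(row)
        else:
            if len(candidates) > 1:
                ties += 1
                counts = np.array([hap_totals[c] for c in candidates])
                candidates = candidates[counts == counts.max()]
            idx = int(candidates[0])
        assignment[aln.sample_ids[i]] = hap_names[idx]
        used_rule[aln.sample_ids[i]] = True
        hap_totals[idx] += 1

    pops = aln.population_set
    counts = pd.DataFrame(0, index=hap_names, columns=pops, dtype=int)
    for sid, pop in zip(aln.sample_ids, aln.populations):
        counts.loc[assignment[sid], pop] += 1

    table = HaplotypeTable(counts)
    return table, HaplotypeAssignment(assignment, used_rule, ties)
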