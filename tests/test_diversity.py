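"""Diversity statistics: haplotype/nucleotide diversity, P-h, Fst."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplodrift import (
    Alignment,
    fst_haplotype,
    haplotype_diversity,
    haplotype_summary,
    load_printed_table,
    nucleotide_diversity,
    summarize_populations,
)
from haplodrift.alignment import encode_sequence

from brute import haplotype_diversity_pairs, mean_pairwise


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((34, 1, 1), 0.11),  # Germany cyt-b
            ((9, 4, 1, 1), 0.60),  # France cyt-b
            ((112, 25, 1, 3, 1, 8, 3, 1, 1), 0.45),  # Germany D-loop
        ],
    )
    def test_printed_values(self, counts, expected):
        assert round(haplotype_diversity(counts), 2) == expected

    def test_single_haplotype_is_zero(self):
        assert haplotype_diversity([17]) == 0.0

    def test_n_below_two_not_applicable(self):
        assert haplotype_diversity([1]) is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=12), min_size=1, max_size=6)
    )
    def test_equals_pair_enumeration(self, counts):
        if sum(counts) < 2:
            return
        expected = haplotype_diversity_pairs(counts)
        assert haplotype_diversity(counts) == pytest.approx(expected, abs=1e-12)


class TestHaplotypeSummary:
    def test_private_haplotypes_continent_level(self):
        table = load_printed_table("cytb")
        # Europe shares C1-C3 with other continents; C4-C6 are private
        assert haplotype_summary(table, "Europe") == (6, 3)
        assert haplotype_summary(table, "Africa") == (4, 2)

    def test_private_haplotypes_country_level(self):
        table = load_printed_table("cytb")
        assert haplotype_summary(table, "Germany") == (3, 0)
        assert haplotype_summary(table, "China") == (24, 23)
        assert haplotype_summary(table, "France") == (4, 2)

    def test_asia_haplotype_number(self):
        table = load_printed_table("cytb")
        h, _ = haplotype_summary(table, "Asia")
        assert h == 32

    def test_dloop_private_haplotypes(self):
        table = load_printed_table("dloop")
        assert haplotype_summary(table, "Germany") == (9, 6)
        assert haplotype_summary(table, "Asia") == (11, 10)

    def test_single_population_all_private(self, two_pop_table):
        sub = two_pop_table.subset(["popA"])
        h, private = haplotype_summary(sub, "popA")
        assert (h, private) == (2, 2)

    def test_unknown_population(self, two_pop_table):
        with pytest.raises(KeyError):
            haplotype_summary(two_pop_table, "Atlantis")


def aln_from_strings(seqs, pops=None):
    matrix = np.stack([encode_sequence(s) for s in seqs])
    return Alignment(
        [f"s{i}" for i in range(len(seqs))], pops or ["p"] * len(seqs), matrix
    )


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert nucleotide_diversity(aln_from_strings(["ACGT" * 5] * 3)) == 0.0

    def test_single_pair(self):
        a = "A" * 100
        b = "T" * 3 + "A" * 97
        assert nucleotide_diversity(aln_from_strings([a, b])) == pytest.approx(0.03)

    def test_matches_all_pairs_oracle(self, rng):
        matrix = rng.integers(0, 4, size=(4, 30)).astype(np.uint8)
        aln = Alignment([f"s{i}" for i in range(4)], ["p"] * 4, matrix)
        expected = mean_pairwise(matrix) / 30
        assert nucleotide_diversity(aln) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_uses_per_pair_length(self):
        # one partial sequence: differences are normalised per observed pair
        aln = aln_from_strings(["AAAA", "AATT", "??TT"])
        # pairs: (0,1): 2/4, (0,2): 2/2, (1,2): 0/2
        assert nucleotide_diversity(aln) == pytest.approx((0.5 + 1.0 + 0.0) / 3)

    def test_n_below_two_not_applicable(self):
        assert nucleotide_diversity(aln_from_strings(["ACGT"])) is None


class TestFst:
    def test_identical_frequencies_zero(self, rng):
        import pandas as pd
        from haplodrift import HaplotypeTable

        counts = pd.DataFrame({"a": [10, 10], "b": [10, 10]}, index=["H1", "H2"])
        fst, _ = fst_haplotype(HaplotypeTable(counts), "a", "b", 50, seed=0)
        assert fst == 0.0

    def test_fixed_for_different_haplotypes_one(self):
        import pandas as pd
        from haplodrift import HaplotypeTable

        counts = pd.DataFrame({"a": [12, 0], "b": [0, 12]}, index=["H1", "H2"])
        fst, p = fst_haplotype(HaplotypeTable(counts), "a", "b", 200, seed=0)
        assert fst == 1.0
        assert p < 0.05

    def test_both_fixed_same_haplotype(self):
        import pandas as pd
        from haplodrift import HaplotypeTable

        counts = pd.DataFrame({"a": [12], "b": [9]}, index=["H1"])
        assert fst_haplotype(HaplotypeTable(counts), "a", "b", 50, 0) == (0.0, 1.0)

    def test_germany_france_formula_oracle(self):
        # direct hand evaluation of (H_T - H_S)/H_T on the printed counts
        table = load_printed_table("cytb")
        fst, _ = fst_haplotype(table, "Germany", "France", permutations=10, seed=1)
        ca = table.counts["Germany"].to_numpy(float)
        cb = table.counts["France"].to_numpy(float)

        def gene_div(c):
            n = c.sum()
            p = c / n
            return n / (n - 1) * (1 - (p**2).sum())

        ht = gene_div(ca + cb)
        hs = (36 * gene_div(ca) + 15 * gene_div(cb)) / 51
        assert fst == pytest.approx((ht - hs) / ht, abs=1e-12)

    def test_null_pvalues_roughly_uniform(self, rng):
        # resample two populations from one pooled spectrum: p should not
        # concentrate near 0
        import pandas as pd
        from haplodrift import HaplotypeTable

        pooled = np.array([30, 25, 20, 15, 10])
        pvals = []
        for i in range(40):
            labels = np.repeat(np.arange(5), pooled)
            rng.shuffle(labels)
            a = np.bincount(labels[:50], minlength=5)
            b = np.bincount(labels[50:], minlength=5)
            counts = pd.DataFrame({"a": a, "b": b})
            counts.index = [f"H{j}" for j in range(5)]
            counts = counts[counts.sum(axis=1) > 0]
            fst, p = fst_haplotype(HaplotypeTable(counts), "a", "b", 99, seed=i)
            pvals.append(p)
        assert 0.25 < np.mean(pvals) < 0.75
        assert np.mean(np.array(pvals) < 0.05) < 0.2


class TestSummaryTable:
    def test_matches_printed_frequency_columns(self):
        table = load_printed_table("cytb")
        summary = summarize_populations(table, level="country")
        germany = summary.loc["Germany"]
        assert germany["n"] == 36
        assert germany["h"] == 3
        assert germany["P-h"] == 0
        assert germany["h.d."] == 0.11
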