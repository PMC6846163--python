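"""The six complexity measures: exact examples, algebra and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from nucleoscore.fixtures import iid_dna, periodic, shuffled
from nucleoscore.measures import (
    MeasureSpec,
    bdm_score,
    compute,
    ctm_score,
    entropy_rate,
    ld_score,
    lzw_length,
    map_to_table_alphabet,
    shannon_entropy,
    supported_block_len,
)
from nucleoscore.transforms import SymbolSequence, to_ry

dna_text = st.text(alphabet="ACGT", min_size=2, max_size=400)


class TestEntropy:
    @pytest.mark.parametrize(
        "s,k,expected",
        [
            ("AAAA", 1, 0.0),
            ("ACGT", 1, 2.0),
            # overlapping 2-blocks of ACAC: AC, CA, AC
            ("ACAC", 2, -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)),
        ],
    )
    def test_examples(self, s, k, expected):
        assert shannon_entropy(s, k) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(dna_text, st.integers(1, 3))
    def test_bounds(self, s, k):
        if len(s) < k:
            return
        h = shannon_entropy(s, k)
        assert -1e-12 <= h <= k * 2.0 + 1e-12

    def test_rate_of_constant_is_zero(self):
        assert entropy_rate("A" * 1000) == 0.0

    def test_rate_of_period_two_repeat_is_zero(self):
        assert entropy_rate("AC" * 5000) == pytest.approx(0.0, abs=0.01)

    def test_rate_of_iid_uniform_approaches_two_bits(self):
        seq = iid_dna(100_000, gc=0.5, seed=11)
        assert entropy_rate(seq.symbols) == pytest.approx(2.0, abs=0.02)

    def test_shuffle_invariance_of_unigram_entropy(self):
        seq = iid_dna(500, seed=3)
        assert shannon_entropy(seq.symbols, 1) == pytest.approx(
            shannon_entropy(shuffled(seq, 5).symbols, 1), abs=1e-12
        )


class TestLZW:
    def test_single_symbol_is_one_code(self):
        assert lzw_length("A") == 1

    def test_repeat_shorter_than_average_random_8mer(self):
        repeat = lzw_length("AAAAAAAA", alphabet="ACGT")
        total = 0
        bases = "ACGT"
        for i in range(4**8):
            s = "".join(bases[(i >> (2 * j)) & 3] for j in range(8))
            total += lzw_length(s, alphabet="ACGT")
        assert repeat < total / 4**8

    @settings(deadline=None, derandomize=True)
    @given(dna_text)
    def test_monotone_in_prefix_length(self, s):
        lengths = [lzw_length(s[: i + 1], alphabet="ACGT") for i in range(len(s))]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))


class TestCTM:
    def test_most_frequent_string_scores_minimum(self, dist22, table22):
        top = max(dist22.counts, key=dist22.counts.get)
        assert table22.entries[top][0] == min(v[0] for v in table22.entries.values())

    def test_definitional_roundtrip(self, dist22, table22):
        bits = ctm_score("01", table22)
        assert bits == -math.log2(dist22.counts["01"] / dist22.total_halting)

    def test_binary_symbols_score_equally(self, table22):
        assert ctm_score("0", table22) == ctm_score("1", table22)

    def test_too_long_rejected(self, table22):
        with pytest.raises(ValueError, match="max_len"):
            ctm_score("0" * 13, table22)

    def test_dna_maps_onto_nonblank_symbols(self, toy_table):
        assert map_to_table_alphabet(SymbolSequence.dna("ACGT"), toy_table) == "1234"

    def test_ry_maps_onto_binary(self, table22):
        seq = to_ry(SymbolSequence.dna("AGCT"))
        assert map_to_table_alphabet(seq, table22) == "0011"


class TestBDMAlgebra:
    def test_single_block_equals_ctm(self, toy_table):
        s = SymbolSequence.dna("ACAC" * 3)  # "121212121212"
        assert bdm_score(s, toy_table) == ctm_score(s, toy_table) == 6.0

    def test_k_copy_law(self, toy_table):
        s = SymbolSequence.dna(("ACAC" * 3) * 8)
        assert bdm_score(s, toy_table) == pytest.approx(6.0 + 3.0)

    def test_disjoint_block_additivity(self, toy_table):
        a = SymbolSequence.dna("AAAA" * 3)  # block "1"*12
        b = SymbolSequence.dna("ACGT" * 3)  # block "1234"*3
        ab = SymbolSequence.dna(a.symbols + b.symbols)
        assert bdm_score(ab, toy_table) == pytest.approx(
            bdm_score(a, toy_table) + bdm_score(b, toy_table)
        )

    def test_remainder_block_kept(self, toy_table):
        s = SymbolSequence.dna("AAAA" * 3 + "TT")  # 12-block + "44" remainder
        assert bdm_score(s, toy_table) == pytest.approx(5.0 + 1.0)

    def test_missing_block_gets_fallback(self, toy_table):
        s = SymbolSequence.dna("GGGGGGGGGGGG")  # absent from toy table
        assert bdm_score(s, toy_table) == toy_table.max_ctm + 1.0

    def test_not_shuffle_invariant(self, table25):
        seq = periodic("ACGT", 36)
        shuf = shuffled(seq, seed=9)
        assert bdm_score(seq, table25, 6) != bdm_score(shuf, table25, 6)

    def test_tracks_block_entropy_on_iid_sequences(self, table25):
        # entropy-approximation regime: across composition gradients, BDM
        # per block and block entropy move together
        seqs = [iid_dna(1200, gc=g, seed=21) for g in np.linspace(0.1, 0.9, 9)]
        bdms = [bdm_score(s, table25, 6) for s in seqs]
        ents = [shannon_entropy(s.symbols, 1) for s in seqs]
        assert spearmanr(bdms, ents).statistic > 0.8


class TestLogicalDepth:
    def test_single_block_is_its_runtime(self, toy_table):
        assert ld_score(SymbolSequence.dna("ACAC" * 3), toy_table) == 30

    def test_multiplicity_aggregation(self, toy_table):
        s = SymbolSequence.dna(("ACAC" * 3) * 5)
        assert ld_score(s, toy_table) == 5 * 30

    def test_missing_block_uses_median_runtime(self, toy_table):
        s = SymbolSequence.dna("GGGGGGGGGGGG")
        assert ld_score(s, toy_table) == toy_table.median_runtime

    def test_requires_runtime_data(self, toy_table):
        from nucleoscore.tm_engine import CTMTable

        stripped = CTMTable(5, {k: (v[0], None) for k, v in toy_table.entries.items()}, 12)
        with pytest.raises(ValueError, match="runtime"):
            ld_score(SymbolSequence.dna("ACGT"), stripped)

    def test_anticorrelated_with_bdm_across_structure_gradient(self, table25):
        bl = supported_block_len(table25)
        population = [iid_dna(147, seed=s) for s in range(8)] + [
            SymbolSequence((m * 147)[:147])
            for m in ("A", "AT", "AAT", "AC", "ACGT", "AATT", "AG", "T")
        ]
        bdms = [bdm_score(s, table25, bl) for s in population]
        lds = [ld_score(s, table25, bl) for s in population]
        assert spearmanr(bdms, lds).statistic < 0


class TestSpecs:
    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            MeasureSpec("kolmogorov")

    def test_table_required_for_algorithmic_measures(self):
        with pytest.raises(ValueError, match="table"):
            MeasureSpec("bdm")

    def test_compute_dispatch_matches_direct_calls(self, table25):
        seq = iid_dna(60, seed=2)
        assert compute(seq, MeasureSpec("entropy", k=2)) == shannon_entropy(seq, 2)
        assert compute(seq, MeasureSpec("lzw")) == lzw_length(seq)
        assert compute(seq, MeasureSpec("bdm", table=table25)) == bdm_score(seq, table25)

    def test_supported_block_len_is_covered(self, table25):
        bl = supported_block_len(table25)
        assert 4 <= bl <= 8
        assert table25.coverage(bl) >= 0.5
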