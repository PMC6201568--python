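"""PFM construction, IUPAC consensus derivation, and mismatch scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phar_regulon import (
    BindingSite,
    IUPACConsensus,
    PHAR_CONSENSUS,
    build_pfm,
    consensus_match_probability,
    count_mismatches,
    derive_iupac_consensus,
    iupac_match,
    reverse_complement,
    scan_sequence,
)
from phar_regulon.motif import IUPAC_SETS, PositionFrequencyMatrix

dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


def naive_mismatches(seq, code_string):
    """Independent oracle: literal IUPAC sets, plain per-position loop."""
    sets = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return sum(1 for b, c in zip(seq, code_string) if b not in sets[c])


class TestBuildPfm:
    def test_small_tally(self):
        pfm = build_pfm([BindingSite("AA"), BindingSite("AC")])
        assert pfm.counts[0].tolist() == [2, 0, 0, 0]
        assert pfm.counts[1].tolist() == [1, 1, 0, 0]
        assert pfm.n_sites == 2

    def test_published_sites_position2_all_G(self, consensus_input_sites):
        pfm = build_pfm(consensus_input_sites)
        assert pfm.counts[1].tolist() == [0, 0, 8, 0]

    def test_single_site_one_hot(self):
        pfm = build_pfm([BindingSite("ACGT")])
        assert np.all(pfm.counts.sum(axis=1) == 1)
        assert derive_iupac_consensus(pfm, 0.5).code_string == "ACGT"

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed length"):
            build_pfm([BindingSite("ACGT"), BindingSite("ACG")])

    def test_column_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            PositionFrequencyMatrix(np.array([[1, 0, 0, 0]]), n_sites=2)


class TestDeriveConsensus:
    def _pfm(self, counts):
        counts = np.asarray(counts)
        return PositionFrequencyMatrix(counts, int(counts.sum(axis=1)[0]))

    def test_two_base_codes(self):
        # A=4,G=4 of 8 -> R; C=4,G=4 of 8 -> S
        pfm = self._pfm([[4, 0, 4, 0], [0, 4, 4, 0]])
        assert derive_iupac_consensus(pfm, 0.25).code_string == "RS"

    def test_below_threshold_base_excluded(self):
        # A=7,C=1 of 8 at min_frequency 0.25 -> A alone
        pfm = self._pfm([[7, 1, 0, 0]])
        assert derive_iupac_consensus(pfm, 0.25).code_string == "A"

    def test_no_base_reaching_threshold_covers_observed(self):
        # three bases at 1/3 each, threshold 0.5 -> code covers all observed
        pfm = self._pfm([[1, 1, 1, 0]])
        assert derive_iupac_consensus(pfm, 0.5).code_string == "V"

    def test_published_sites_vs_published_consensus(self, consensus_input_sites):
        """The 8 printed sites give a code contained in the published
        consensus everywhere and identical at 11 of 12 positions."""
        pfm = build_pfm(consensus_input_sites)
        derived = derive_iupac_consensus(pfm, 0.25)
        contained = [
            IUPAC_SETS[d] <= IUPAC_SETS[p]
            for d, p in zip(derived.code_string, PHAR_CONSENSUS)
        ]
        assert all(contained)
        identical = sum(d == p for d, p in zip(derived.code_string, PHAR_CONSENSUS))
        assert identical >= 11

    def test_soundness_at_low_threshold(self, consensus_input_sites):
        """With min_frequency <= 1/n every input site matches exactly."""
        pfm = build_pfm(consensus_input_sites)
        derived = derive_iupac_consensus(pfm, 1 / 8)
        for site in consensus_input_sites:
            assert count_mismatches(site.sequence, derived) == 0


class TestIupacMatch:
    @pytest.mark.parametrize(
        "base,code,expected",
        [("A", "R", True), ("G", "R", True), ("C", "R", False),
         ("C", "S", True), ("A", "N", True), ("N", "N", False),
         ("N", "A", False), ("T", "Y", True)],
    )
    def test_semantics(self, base, code, expected):
        assert iupac_match(base, code) is expected

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("A", "Z")
        with pytest.raises(ValueError):
            iupac_match("Q", "A")


class TestCountMismatches:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TGCGACGCACAA", 0),   # the pckA/phaP1 site
         ("CGCATCGCAGCA", 1),   # the phaZ1 site: position 1
         ("TGCANNNNNNNN", 8)],  # N never matches
    )
    def test_against_published_consensus(self, seq, expected):
        assert count_mismatches(seq, PHAR_CONSENSUS) == expected

    def test_consensus_expansion_member_matches(self):
        # lexicographically smallest ACGT expansion of the consensus
        member = "".join(sorted(IUPAC_SETS[c])[0] for c in PHAR_CONSENSUS)
        assert count_mismatches(member, PHAR_CONSENSUS) == 0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            count_mismatches("ACGT", PHAR_CONSENSUS)


class TestScanSequence:
    def test_planted_site_found_at_offset(self):
        rng = np.random.default_rng(5)
        background = "".join(rng.choice(list("ACGT"), 80))
        seq = background[:30] + "TGCGACGCACAA" + background[30:]
        hits = scan_sequence(seq, PHAR_CONSENSUS, max_mismatch=0)
        assert [h.offset for h in hits if h.strand == "+"] == [30]

    def test_region_shorter_than_consensus(self):
        assert scan_sequence("ACGT", PHAR_CONSENSUS) == []

    def test_overlapping_hits_all_reported(self):
        # two exact sites overlapping by sharing no bases, plus strand
        seq = "TGCGACGCACAA" + "TGCGACGCACAA"
        offsets = [h.offset for h in scan_sequence(seq, PHAR_CONSENSUS, 0, both_strands=False)]
        assert offsets == [0, 12]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dna)
    def test_oracle_equivalence_small(self, seq):
        for strand_flag in (False, True):
            hits = scan_sequence(seq, PHAR_CONSENSUS, 1, both_strands=strand_flag)
            expected = []
            for off in range(len(seq) - 11):
                win = seq[off : off + 12]
                if naive_mismatches(win, PHAR_CONSENSUS) <= 1:
                    expected.append((off, "+"))
                if strand_flag and naive_mismatches(
                    reverse_complement(win), PHAR_CONSENSUS
                ) <= 1:
                    expected.append((off, "-"))
            assert sorted((h.offset, h.strand) for h in hits) == sorted(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dna, st.integers(min_value=0, max_value=3))
    def test_budget_monotonicity(self, seq, k):
        smaller = {(h.offset, h.strand) for h in scan_sequence(seq, PHAR_CONSENSUS, k)}
        larger = {(h.offset, h.strand) for h in scan_sequence(seq, PHAR_CONSENSUS, k + 1)}
        assert smaller <= larger

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dna)
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement swaps strands and mirrors offsets."""
        fwd = scan_sequence(seq, PHAR_CONSENSUS, 1)
        rev = scan_sequence(reverse_complement(seq), PHAR_CONSENSUS, 1)
        n = len(seq)
        mirrored = {
            (n - 12 - h.offset, "+" if h.strand == "-" else "-") for h in rev
        }
        assert {(h.offset, h.strand) for h in fwd} == mirrored


class TestMatchProbability:
    def test_against_exhaustive_enumeration(self):
        """Brute-force enumeration of all L-mers for a short consensus."""
        from itertools import product

        code = "ARN"
        for budget in (0, 1, 2):
            exact = sum(
                naive_mismatches("".join(w), code) <= budget
                for w in product("ACGT", repeat=3)
            ) / 64
            assert consensus_match_probability(code, budget) == pytest.approx(exact)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            IUPACConsensus("ACGZ")
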