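from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutpep import (
    ActivityEntry,
    ActivityReference,
    DomainError,
    cleavage_sites,
    default_enzymes,
    digest,
    load_enzyme_table,
    release_frequency,
    theoretical_dh,
    total_release_frequency,
)
from .conftest import brute_force_cut_sites, random_sequence


class TestEnzymeTable:
    def test_pinned_digestive_tract_rules(self):
        table = load_enzyme_table()
        assert table["pepsin_ph_gt2"].p1_residues == frozenset("FL")
        assert table["pepsin_ph_gt2"].biopep_id == 39
        assert table["trypsin"].p1_residues == frozenset("KR")
        assert table["trypsin"].biopep_id == 12
        assert table["chymotrypsin_a"].p1_residues == frozenset("FYW")
        assert table["chymotrypsin_a"].biopep_id == 11

    def test_custom_table_round_trip(self, tmp_path):
        p = tmp_path / "enzymes.tsv"
        p.write_text(
            "name\tec_number\tbiopep_id\tp1_residues\tp1prime_exclusions\n"
            "tryp_no_p\t3.4.21.4\t12\tKR\tP\n"
        )
        rule = load_enzyme_table(p)["tryp_no_p"]
        assert rule.p1prime_exclusions == frozenset("P")
        # K-P bond resists, K-G bond cuts
        assert cleavage_sites("AKPG", [rule]) == []
        assert cleavage_sites("AKGP", [rule]) == [2]

    def test_unknown_enzyme_name(self):
        with pytest.raises(DomainError):
            default_enzymes(["subtilisin"])


class TestCleavageSites:
    def test_trypsin_hand_enumeration(self, trypsin):
        assert cleavage_sites("AKVWKG", trypsin) == [2, 5]

    def test_three_enzyme_union(self, gut_enzymes):
        # L at 2, K at 3, F at 5 cut; R at 6 is C-terminal (no bond)
        assert cleavage_sites("MLKAFR", gut_enzymes) == [2, 3, 5]

    def test_no_susceptible_residues(self, trypsin):
        assert cleavage_sites("AGSTAG", trypsin) == []

    def test_empty_enzyme_list_is_domain_error(self):
        with pytest.raises(DomainError):
            cleavage_sites("AKVWKG", [])


class TestDigest:
    def test_trypsin_fragments(self, trypsin):
        result = digest("AKVWKG", trypsin)
        assert [f for f, _, _ in result.fragments] == ["AK", "VWK", "G"]
        assert result.d_bonds == 2 and result.D_bonds == 5

    def test_three_enzyme_fragments(self, gut_enzymes):
        result = digest("MLKAFR", gut_enzymes)
        assert [f for f, _, _ in result.fragments] == ["ML", "K", "AF", "R"]
        assert result.d_bonds == 3 and result.D_bonds == 5

    def test_single_residue_chain(self, trypsin):
        result = digest("A", trypsin)
        assert result.fragments == (("A", 1, 1),)
        assert result.d_bonds == 0 and result.D_bonds == 0

    def test_fragment_coordinates_match_sequence(self, gut_enzymes):
        seq = "MLKAFRWYPKGA"
        result = digest(seq, gut_enzymes)
        for frag, start, end in result.fragments:
            assert seq[start - 1 : end] == frag


class TestTheoreticalDH:
    def test_worked_percentage(self, trypsin):
        assert theoretical_dh(digest("AKVWKG", trypsin)) == pytest.approx(40.0)

    def test_zero_and_full_hydrolysis(self, trypsin):
        assert theoretical_dh(digest("AGSTAG", trypsin)) == 0.0
        assert theoretical_dh(digest("KKKK", trypsin)) == pytest.approx(100.0)

    def test_single_residue_is_error_not_zero(self, trypsin):
        with pytest.raises(DomainError):
            theoretical_dh(digest("A", trypsin))


class TestReleaseFrequency:
    def test_released_fragment_counts(self, trypsin):
        ref = ActivityReference([ActivityEntry("VWK", "ACE")])
        assert release_frequency("AKVWKG", trypsin, ref, "ACE") == Fraction(1, 6)

    def test_bisected_peptide_contributes_nothing(self, trypsin):
        # VWK occurs in the chain but trypsin cuts after its internal K
        ref = ActivityReference([ActivityEntry("VKW", "ACE")])
        assert "VKW" in "AVKWG"
        assert release_frequency("AVKWG", trypsin, ref, "ACE") == 0

    def test_repeated_release(self, trypsin):
        ref = ActivityReference([ActivityEntry("VWK", "ACE")])
        assert release_frequency("VWKVWK", trypsin, ref, "ACE") == Fraction(2, 6)

    def test_total_release_sums_disjoint_activities(self, trypsin):
        ref = ActivityReference(
            [ActivityEntry("VWK", "ACE"), ActivityEntry("YPK", "DPP-IV")]
        )
        seq = "AKVWKGYPK"  # trypsin releases VWK and... enumerate: cuts after K2, K5, K9
        assert [f for f, _, _ in digest(seq, trypsin).fragments] == ["AK", "VWK", "GYPK"]
        assert total_release_frequency(seq, trypsin, ref, min_fragment_length=2) == Fraction(1, 9)
        assert release_frequency(seq, trypsin, ref, "ACE") == Fraction(1, 9)
        assert release_frequency(seq, trypsin, ref, "DPP-IV") == 0


class TestDigestProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_conservation_and_site_oracle(self, seed):
        enzymes = default_enzymes()
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 300)
        result = digest(seq, enzymes)
        assert "".join(f for f, _, _ in result.fragments) == seq
        assert list(result.cut_sites) == brute_force_cut_sites(seq, enzymes)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_under_enzyme_addition(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 300)
        names = ["pepsin_ph_gt2", "trypsin", "chymotrypsin_a"]
        prev_sites: set[int] = set()
        for k in range(1, 4):
            result = digest(seq, default_enzymes(names[:k]))
            sites = set(result.cut_sites)
            assert prev_sites <= sites  # d never decreases
            prev_sites = sites

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_released_fragments_resist_redigestion(self, seed):
        enzymes = default_enzymes()
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 200)
        for frag, _, _ in digest(seq, enzymes).fragments:
            again = digest(frag, enzymes)
            assert [f for f, _, _ in again.fragments] == [frag]
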