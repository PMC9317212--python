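import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutpep import (
    DomainError,
    EpitopeInput,
    EpitopeRegion,
    ProteinRecord,
    cross_species_hits,
    generate_epitope_scenario,
    locate_exact,
    merge_regions,
    preprocess_epitope_set,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _protein(seq, acc="P1", name=""):
    return ProteinRecord(accession=acc, allergen_name=name or acc, sequence=seq)


class TestLocateExact:
    def test_single_occurrence_coordinates(self):
        protein = _protein("G" * 11 + "QWERTY" + "G" * 5)
        (region,) = locate_exact(EpitopeInput("e1", "QWERTY", "P1"), protein)
        assert (region.start, region.end) == (12, 17)
        assert region.sequence == "QWERTY"

    def test_absent_epitope(self):
        assert locate_exact(EpitopeInput("e1", "QWERTY", "P1"), _protein("GGGG")) == []

    def test_duplicate_occurrences_sorted(self):
        protein = _protein("AAKVWAAAKVWAA")
        regions = locate_exact(EpitopeInput("e1", "KVW", "P1"), protein)
        assert [(r.start, r.end) for r in regions] == [(3, 5), (9, 11)]


class TestCrossSpeciesHits:
    def test_exact_match_scores_pam30_diagonal(self):
        # PAM30 diagonal: A=6, K=7, V=7, W=13 -> 33
        protein = _protein("GGAKVWGG")
        (hit,) = cross_species_hits(EpitopeInput("e1", "AKVW", "P1"), [protein], 1.0)
        assert hit.score == 33
        assert (hit.subject_start, hit.subject_end) == (3, 6)
        assert hit.identity_fraction == 1.0

    def test_self_alignment_recovers_exact_location(self):
        seq = "MKLVINSEQWERTYPLMHACDEF"
        protein = _protein(seq)
        epitope = EpitopeInput("e1", seq[5:14], "P1")
        (hit,) = cross_species_hits(epitope, [protein], 1.0)
        (region,) = locate_exact(epitope, protein)
        assert (hit.subject_start, hit.subject_end) == (region.start, region.end)

    def test_substitution_drops_below_full_identity(self):
        epitope = EpitopeInput("e1", "AKVWDE", "P1")
        protein = _protein("GGAKVWCEGG")  # D->C substitution
        assert cross_species_hits(epitope, [protein], 1.0) == []
        # best local alignment stops before the costly D->C column: 4/6 identical
        hits = cross_species_hits(epitope, [protein], 0.6)
        assert hits and hits[0].identity_fraction == pytest.approx(4 / 6)

    def test_epitope_below_seeding_length_rejected(self):
        from nutpep import ValidationError

        with pytest.raises(ValidationError):
            EpitopeInput("e1", "VW", "P1")

    def test_min_identity_bounds(self):
        with pytest.raises(DomainError):
            cross_species_hits(EpitopeInput("e1", "AKVW", "P1"), [], 0.0)


class TestMergeRegions:
    @staticmethod
    def _regions(protein_seq, intervals, ids=None):
        ids = ids or [f"e{i}" for i in range(len(intervals))]
        return [
            EpitopeRegion("P1", a, b, protein_seq[a - 1 : b], (i,))
            for (a, b), i in zip(intervals, ids)
        ]

    def test_overlap_and_adjacency_chain_to_one(self):
        seq = "".join(AA[i % 20] for i in range(60))
        regions = self._regions(seq, [(10, 24), (20, 35), (36, 50)])
        (merged,) = merge_regions(regions)
        assert (merged.start, merged.end) == (10, 50)
        assert merged.sequence == seq[9:50]
        assert merged.member_ids == ("e0", "e1", "e2")

    def test_one_residue_gap_does_not_merge(self):
        seq = "ACDEFGHIK"
        regions = self._regions(seq, [(1, 5), (7, 9)])
        assert len(merge_regions(regions)) == 2

    def test_single_region_unchanged(self):
        seq = "ACDEFGHIK"
        regions = self._regions(seq, [(2, 6)])
        assert merge_regions(regions) == regions

    def test_mixed_proteins_rejected(self):
        a = EpitopeRegion("P1", 1, 3, "ACD", ("e0",))
        b = EpitopeRegion("P2", 1, 3, "ACD", ("e1",))
        with pytest.raises(DomainError):
            merge_regions([a, b])

    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_idempotent_order_invariant_coverage_preserving(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AA), size=120))
        n = int(rng.integers(1, 12))
        intervals = []
        for _ in range(n):
            a = int(rng.integers(1, 110))
            b = min(120, a + int(rng.integers(0, 25)))
            intervals.append((a, b))
        regions = self._regions(seq, intervals)
        merged = merge_regions(regions)
        # coverage preservation
        cover = lambda rs: {p for r in rs for p in range(r.start, r.end + 1)}
        assert cover(merged) == cover(regions)
        # pairwise non-overlapping, non-adjacent, sorted
        for r1, r2 in zip(merged, merged[1:]):
            assert r2.start > r1.end + 1
        # sequence field consistency
        for r in merged:
            assert r.sequence == seq[r.start - 1 : r.end]
        # idempotence and order invariance
        assert merge_regions(merged) == merged
        perm = [regions[i] for i in rng.permutation(len(regions))]
        assert merge_regions(perm) == merged


class TestPreprocess:
    def test_tiling_epitopes_merge_to_one_region(self):
        record, epitopes, truth = generate_epitope_scenario(
            protein_length=150, n_epitopes=3, overlap_profile="chained", seed=7
        )
        regions = preprocess_epitope_set(epitopes, [record])
        assert regions == truth.expected_regions
        assert len(regions) == 1

    def test_no_placements_warns_and_returns_empty(self, caplog):
        protein = _protein("GGGGGGGG")
        epitope = EpitopeInput("e1", "QWERTY", "MissingAllergen")
        with caplog.at_level("WARNING", logger="nutpep"):
            assert preprocess_epitope_set([epitope], [protein]) == []
        assert any("MissingAllergen" in r.message for r in caplog.records)

    def test_shared_substring_maps_to_both_proteins(self):
        shared = "QWERTYHIKL"
        p1 = _protein("AAA" + shared + "CCC", acc="P1")
        p2 = _protein("DDDDD" + shared + "EE", acc="P2")
        epitope = EpitopeInput("e1", shared, "P1")
        regions = preprocess_epitope_set([epitope], [p1, p2])
        assert {r.protein_id for r in regions} == {"P1", "P2"}

    def test_exact_agreement_between_alignment_and_substring_transfer(self):
        """Planted-substring placements agree between SW identity 1.0 and exact search."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = "".join(rng.choice(list(AA), size=80))
            start = int(rng.integers(0, 60))
            epitope = EpitopeInput("e1", seq[start : start + 12], "other")
            protein = _protein(seq, acc="P2")
            exact = locate_exact(epitope, protein)
            hits = cross_species_hits(epitope, [protein], 1.0)
            assert hits
            assert (hits[0].subject_start, hits[0].subject_end) in [
                (r.start, r.end) for r in exact
            ]
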