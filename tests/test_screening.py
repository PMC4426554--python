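"""Prescription-list expansion and interaction screening."""

import random

import pytest

from ddicompare.normalization import CanonicalPair, NormalizedDdiSet
from ddicompare.screening import (
    PrescriptionList,
    ResolutionError,
    expand_to_ingredient_pairs,
    filter_systemic,
    read_prescriptions,
    screen,
    top_pairs,
)
from ddicompare.source_ingest import Source


def make_set(pairs, source=Source.NDFRT):
    return NormalizedDdiSet(source=source, pairs=set(pairs))


class TestFilterSystemic:
    def test_topicals_removed_order_preserved(self, term):
        plist = PrescriptionList("p1", ("D_PRIM", "D_HYDR", "D_LOVA"))
        out = filter_systemic(plist, term)
        assert out.drugs == ("D_PRIM", "D_LOVA")

    def test_all_systemic_unchanged(self, term):
        plist = PrescriptionList("p1", ("D_PRIM", "D_LOVA"))
        assert filter_systemic(plist, term).drugs == plist.drugs

    def test_all_topical_yields_none(self, term):
        assert filter_systemic(PrescriptionList("p1", ("D_HYDR",)), term) is None

    def test_unknown_id_raises_with_context(self, term):
        with pytest.raises(ResolutionError, match="D_NOPE"):
            filter_systemic(PrescriptionList("p1", ("D_NOPE",)), term)

    def test_ingredient_id_rejected(self, term):
        with pytest.raises(ResolutionError):
            filter_systemic(PrescriptionList("p1", ("I_PRIM",)), term)


class TestExpand:
    def test_combination_product_worked_example(self, term):
        # Primidone tablet + carbidopa/levodopa combination -> two pairs
        plist = PrescriptionList("p1", ("D_PRIM", "D_CALE"))
        pairs = expand_to_ingredient_pairs(plist, term)
        assert pairs == {
            CanonicalPair("I_CARB", "I_PRIM"),
            CanonicalPair("I_LEVO", "I_PRIM"),
        }

    def test_single_drug_no_pairs(self, term):
        assert expand_to_ingredient_pairs(PrescriptionList("p1", ("D_PRIM",)), term) == set()

    def test_n_single_ingredient_drugs_give_n_choose_2(self, term):
        plist = PrescriptionList("p1", ("D_PRIM", "D_LOVA", "D_DILT", "D_AMOX"))
        assert len(expand_to_ingredient_pairs(plist, term)) == 6

    def test_duplicate_drugs_collapse(self, term):
        plist = PrescriptionList("p1", ("D_PRIM", "D_PRIM", "D_LOVA"))
        assert len(expand_to_ingredient_pairs(plist, term)) == 1


class TestScreen:
    def lists(self, term):
        return [
            PrescriptionList("p1", ("D_DILT", "D_LOVA")),          # diltiazem-lovastatin
            PrescriptionList("p2", ("D_DILT", "D_LOVA", "D_HYDR")),  # topical ignored
            PrescriptionList("p3", ("D_AMOX", "D_ETHI")),          # amoxicillin-EE
            PrescriptionList("p4", ("D_PRIM", "D_CALE")),
        ]

    def sources(self):
        both = CanonicalPair("I_DILT", "I_LOVA")
        b_only = CanonicalPair("I_AMOX", "I_ETHI")
        a = make_set({both}, Source.NDFRT)
        b = make_set({both, b_only}, Source.DRUGBANK)
        return a, b

    def test_matching_and_frequencies(self, term):
        a, b = self.sources()
        result = screen(self.lists(term), [a, b], term)
        both = CanonicalPair("I_DILT", "I_LOVA")
        assert result.pair_frequency[both] == 2
        assert result.per_source_matches["NDFRT"].total == 2
        assert result.per_source_matches["NDFRT"].unique == 1
        assert result.per_source_matches["DRUGBANK"].total == 3
        assert result.per_source_matches["DRUGBANK"].unique == 2
        assert result.both_sources.total == 2
        assert result.both_sources.unique == 1

    def test_conservation(self, term):
        result = screen(self.lists(term), list(self.sources()), term)
        assert sum(result.pair_frequency.values()) == result.total_pairs
        assert len(result.pair_frequency) == result.unique_pairs
        # partition of unique matches into A-only / B-only / both
        a_u = result.per_source_matches["NDFRT"].unique
        b_u = result.per_source_matches["DRUGBANK"].unique
        both_u = result.both_sources.unique
        union = len(result.matched_by)
        assert (a_u - both_u) + (b_u - both_u) + both_u == union

    def test_order_invariance(self, term):
        a, b = self.sources()
        base = screen(self.lists(term), [a, b], term)
        rng = random.Random(9)
        for _ in range(3):
            shuffled = self.lists(term)
            rng.shuffle(shuffled)
            again = screen(shuffled, [a, b], term)
            assert again.pair_frequency == base.pair_frequency
            assert again.per_source_matches == base.per_source_matches
            assert again.both_sources == base.both_sources

    def test_empty_stream(self, term):
        result = screen([], list(self.sources()), term)
        assert result.total_pairs == result.unique_pairs == 0
        assert result.both_sources.total == 0

    def test_list_weight_multiplies_occurrences(self, term):
        a, b = self.sources()
        lists = [PrescriptionList("p1", ("D_DILT", "D_LOVA"), weight=5)]
        result = screen(lists, [a, b], term)
        assert result.per_source_matches["NDFRT"].total == 5
        assert result.per_source_matches["NDFRT"].unique == 1


class TestTopPairs:
    def build_result(self, term, freqs):
        lists = []
        drugs_for = {
            CanonicalPair("I_DILT", "I_LOVA"): ("D_DILT", "D_LOVA"),
            CanonicalPair("I_AMOX", "I_ETHI"): ("D_AMOX", "D_ETHI"),
            CanonicalPair("I_LOVA", "I_PRIM"): ("D_PRIM", "D_LOVA"),
        }
        n = 0
        for pair, freq in freqs.items():
            for _ in range(freq):
                n += 1
                lists.append(PrescriptionList(f"p{n}", drugs_for[pair]))
        sources = [make_set(set(freqs), Source.NDFRT)]
        return screen(lists, sources, term)

    def test_sorted_by_frequency(self, term):
        freqs = {
            CanonicalPair("I_DILT", "I_LOVA"): 10,
            CanonicalPair("I_AMOX", "I_ETHI"): 7,
            CanonicalPair("I_LOVA", "I_PRIM"): 3,
        }
        result = self.build_result(term, freqs)
        rows = top_pairs(result, 3)
        assert [r[1] for r in rows] == [10, 7, 3]

    def test_ties_break_lexicographically(self, term):
        freqs = {
            CanonicalPair("I_DILT", "I_LOVA"): 4,
            CanonicalPair("I_AMOX", "I_ETHI"): 4,
        }
        rows = top_pairs(self.build_result(term, freqs), 5)
        assert rows[0][0] == CanonicalPair("I_AMOX", "I_ETHI")

    def test_k_truncates_and_rejects_nonpositive(self, term):
        result = self.build_result(term, {CanonicalPair("I_DILT", "I_LOVA"): 2})
        assert len(top_pairs(result, 1)) == 1
        with pytest.raises(ValueError):
            top_pairs(result, 0)


class TestReadPrescriptions:
    def test_drug_name_resolution_and_grouping(self, term, tmp_path):
        path = tmp_path / "rx.csv"
        path.write_text(
            "patient_id,drug_name\n"
            "p1,Primidone 250 MG Oral Tablet\n"
            "p1,Lovastatin 20 MG Oral Tablet\n"
            "p2,Amoxicillin 500 MG Oral Capsule\n"
        )
        lists = read_prescriptions(path, term)
        assert [(l.patient_id, l.drugs) for l in lists] == [
            ("p1", ("D_PRIM", "D_LOVA")),
            ("p2", ("D_AMOX",)),
        ]

    def test_count_column_sets_weight(self, term, tmp_path):
        path = tmp_path / "rx.csv"
        path.write_text("patient_id,drug_id,count\np1,D_PRIM,3\np1,D_LOVA,3\n")
        (plist,) = read_prescriptions(path, term)
        assert plist.weight == 3

    def test_non_uniform_counts_rejected(self, term, tmp_path):
        path = tmp_path / "rx.csv"
        path.write_text("patient_id,drug_id,count\np1,D_PRIM,3\np1,D_LOVA,2\n")
        with pytest.raises(ValueError, match="non-uniform"):
            read_prescriptions(path, term)

    def test_unknown_name_raises(self, term, tmp_path):
        path = tmp_path / "rx.csv"
        path.write_text("patient_id,drug_name\np1,nosuchproduct\n")
        with pytest.raises(ResolutionError):
            read_prescriptions(path, term)
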