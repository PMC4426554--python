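"""Overlap reports, reference-group coverage and severity stratification."""

import pytest
from hypothesis import given, settings, strategies as st

from ddicompare.comparison import (
    compare_sets,
    coverage_of_reference,
    round_percent,
    severity_stratified_coverage,
)
from ddicompare.normalization import CanonicalPair, NormalizedDdiSet
from ddicompare.source_ingest import ReferenceGroup, Severity, Source


def make_set(pairs, source=Source.NDFRT, severities=None):
    return NormalizedDdiSet(
        source=source, pairs=set(pairs), severity_of=severities or {}
    )


def pair(i, j):
    return CanonicalPair(f"I{min(i, j):03d}", f"I{max(i, j):03d}")


class TestRoundPercent:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (207, 360, 58),
            (211, 360, 59),
            (146, 207, 71),
            (146, 211, 69),
            (2801, 9392, 30),
            (2801, 11552, 24),
            (328, 360, 91),
            (0, 7, 0),
            (7, 7, 100),
            (1, 200, 1),   # 0.5 rounds half-up
        ],
    )
    def test_printed_coverage_roundings(self, num, den, expected):
        assert round_percent(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            round_percent(1, 0)

    def test_numerator_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            round_percent(5, 4)


class TestCompareSets:
    def test_identical_sets(self):
        s = make_set({pair(1, 2), pair(3, 4)})
        report = compare_sets(s, make_set(s.pairs, Source.DRUGBANK))
        assert report.shared == 2
        assert report.only_a == report.only_b == 0
        assert report.coverage_a_by_b_pct == report.coverage_b_by_a_pct == 100

    def test_disjoint_sets(self):
        report = compare_sets(
            make_set({pair(1, 2)}), make_set({pair(3, 4)}, Source.DRUGBANK)
        )
        assert report.shared == 0
        assert report.coverage_a_by_b_pct == 0

    @given(
        st.sets(st.tuples(st.integers(0, 15), st.integers(0, 15)).filter(lambda t: t[0] != t[1]), max_size=30),
        st.sets(st.tuples(st.integers(0, 15), st.integers(0, 15)).filter(lambda t: t[0] != t[1]), max_size=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_counts_match_brute_force(self, raw_a, raw_b):
        pa = {pair(*t) for t in raw_a}
        pb = {pair(*t) for t in raw_b}
        report = compare_sets(make_set(pa), make_set(pb, Source.DRUGBANK))
        shared_bf = sum(1 for p in pa if p in pb)
        assert report.shared == shared_bf
        assert report.only_a == len(pa) - shared_bf
        assert report.only_b == len(pb) - shared_bf
        assert report.shared + report.only_a == report.size_a
        assert report.shared + report.only_b == report.size_b
        # symmetric up to swapping fields
        mirrored = compare_sets(make_set(pb), make_set(pa, Source.DRUGBANK))
        assert (mirrored.size_a, mirrored.only_a) == (report.size_b, report.only_b)
        # 3-way partition covers the union
        assert report.only_a + report.only_b + report.shared == len(pa | pb)


class TestReferenceCoverage:
    def test_full_single_pair_group(self, term):
        groups = [ReferenceGroup(30, "t-p", ("diltiazem",), ("lovastatin",))]
        source = make_set({CanonicalPair("I_DILT", "I_LOVA")})
        cov = coverage_of_reference(source, groups, term)
        assert cov.groups[0].matched == 1
        assert cov.groups[0].matched_pct == 100
        assert cov.total_matched == 1

    def test_empty_source_matches_nothing(self, term):
        groups = [
            ReferenceGroup(1, "g", ("diltiazem", "omeprazole"), ("lovastatin",))
        ]
        cov = coverage_of_reference(make_set(set()), groups, term)
        assert cov.total_matched == 0
        assert all(g.matched == 0 for g in cov.groups)

    def test_totals_deduplicate_across_groups(self, term):
        # same underlying pair in two groups: counted per group, once in total
        groups = [
            ReferenceGroup(1, "g1", ("diltiazem",), ("lovastatin",)),
            ReferenceGroup(2, "g2", ("diltiazem hydrochloride",), ("lovastatin",)),
        ]
        source = make_set({CanonicalPair("I_DILT", "I_LOVA")})
        cov = coverage_of_reference(source, groups, term)
        assert [g.matched for g in cov.groups] == [1, 1]
        assert cov.total_pairs == 1
        assert cov.total_matched == 1

    def test_totals_match_brute_force_recount(self, term):
        import itertools
        import random

        rng = random.Random(11)
        names = ["diltiazem", "lovastatin", "omeprazole", "clopidogrel",
                 "doxacurium", "zuclopenthixol", "Primidone", "Carbidopa"]
        groups = []
        for gid in range(4):
            objs = tuple(rng.sample(names, rng.randint(1, 3)))
            precs = tuple(rng.sample(names, rng.randint(1, 3)))
            try:
                groups.append(ReferenceGroup(gid, f"g{gid}", objs, precs))
            except Exception:
                continue
        ids = {n: term.to_ingredient(term.lookup(n)) for n in names}
        all_pairs = {
            CanonicalPair(*sorted((ids[a], ids[b])))
            for a, b in itertools.combinations(names, 2)
            if ids[a] != ids[b]
        }
        source_pairs = set(rng.sample(sorted(all_pairs), len(all_pairs) // 2))
        cov = coverage_of_reference(make_set(source_pairs), groups, term)
        ref_union = set()
        for g in groups:
            gp = {
                CanonicalPair(*sorted((ids[o], ids[p])))
                for o in g.object_members for p in g.precipitant_members
                if ids[o] != ids[p]
            }
            row = next(r for r in cov.groups if r.group_id == g.group_id)
            assert row.matched == len(gp & source_pairs)
            ref_union |= gp
        assert cov.total_matched == len(ref_union & source_pairs)


class TestSeverityStratification:
    def test_superset_gives_full_coverage(self):
        pairs = {pair(1, 2), pair(3, 4)}
        sev = {pair(1, 2): Severity.CRITICAL, pair(3, 4): Severity.SIGNIFICANT}
        a = make_set(pairs, severities=sev)
        b = make_set(pairs | {pair(5, 6)}, Source.DRUGBANK)
        assert severity_stratified_coverage(a, b) == {
            Severity.SIGNIFICANT: 100, Severity.CRITICAL: 100
        }

    def test_disjoint_gives_zero(self):
        a = make_set({pair(1, 2)}, severities={pair(1, 2): Severity.CRITICAL})
        b = make_set({pair(3, 4)}, Source.DRUGBANK)
        assert severity_stratified_coverage(a, b) == {Severity.CRITICAL: 0}

    def test_empty_stratum_omitted(self):
        a = make_set({pair(1, 2)}, severities={pair(1, 2): Severity.CRITICAL})
        b = make_set(set(), Source.DRUGBANK)
        assert Severity.SIGNIFICANT not in severity_stratified_coverage(a, b)

    def test_missing_annotation_rejected(self):
        a = make_set({pair(1, 2)})
        with pytest.raises(ValueError, match="severity"):
            severity_stratified_coverage(a, make_set(set(), Source.DRUGBANK))

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_strata_recompose_overall_coverage(self, data):
        n = data.draw(st.integers(1, 20))
        pairs = [pair(2 * i, 2 * i + 1) for i in range(n)]
        sev = {
            p: data.draw(st.sampled_from(list(Severity)), label=f"sev{i}")
            for i, p in enumerate(pairs)
        }
        covered = {
            p for i, p in enumerate(pairs)
            if data.draw(st.booleans(), label=f"cov{i}")
        }
        a = make_set(set(pairs), severities=sev)
        b = make_set(covered, Source.DRUGBANK)
        # exact recomposition before rounding: stratum hits sum to total hits
        total_hits = sum(
            len({p for p, s in sev.items() if s is severity} & covered)
            for severity in Severity
        )
        assert total_hits == len(set(pairs) & covered)
        # and each reported stratum matches a direct recount
        for severity, pct in severity_stratified_coverage(a, b).items():
            stratum = {p for p, s in sev.items() if s is severity}
            assert pct == round_percent(len(stratum & covered), len(stratum))
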