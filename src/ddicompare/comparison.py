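"""Overlap and coverage statistics between normalized interaction sets.

Coverage is always expressed the way DDI surveys print it: an integer
percentage obtained by half-up rounding, e.g. 207 of 360 reference pairs
is 58%.  :func:`compare_sets` reports the mutual coverage of two sources,
:func:`coverage_of_reference` breaks reference-set coverage down by
curation group, and :func:`severity_stratified_coverage` splits one
source's coverage of the other by the annotated severity level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .normalization import CanonicalPair, NormalizedDdiSet, canonical_pair
from .source_ingest import ReferenceGroup, Severity
from .terminology import Terminology, TermType


def round_percent(numerator: int, denominator: int) -> int:
    """100 * numerator / denominator, rounded half-up to an integer.

    Exact integer arithmetic: floor((200 n + d) / 2 d), so 57.5 -> 58.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return (200 * numerator + denominator) // (2 * denominator)


@dataclass(frozen=True)
class OverlapReport:
    size_a: int
    size_b: int
    shared: int
    only_a: int
    only_b: int
    coverage_a_by_b_pct: int
    coverage_b_by_a_pct: int


@dataclass(frozen=True)
class GroupCoverage:
    group_id: int
    label: str
    n_pairs: int
    matched: int
    matched_pct: int


@dataclass(frozen=True)
class ReferenceCoverage:
    """Per-group coverage plus deduplicated totals."""

    groups: tuple[GroupCoverage, ...]
    total_pairs: int
    total_matched: int
    total_pct: int


def compare_sets(a: NormalizedDdiSet, b: NormalizedDdiSet) -> OverlapReport:
    """Exact set algebra on the two sources' canonical pair sets."""
    shared = a.pairs & b.pairs
    return OverlapReport(
        size_a=len(a.pairs),
        size_b=len(b.pairs),
        shared=len(shared),
        only_a=len(a.pairs) - len(shared),
        only_b=len(b.pairs) - len(shared),
        coverage_a_by_b_pct=round_percent(len(shared), len(a.pairs)) if a.pairs else 0,
        coverage_b_by_a_pct=round_percent(len(shared), len(b.pairs)) if b.pairs else 0,
    )


def _group_canonical_pairs(
    group: ReferenceGroup, term: Terminology
) -> set[CanonicalPair]:
    """Resolve one group's cross-product to canonical ingredient pairs.

    Members that do not resolve to an ingredient-level concept are skipped;
    pairs collapsing to a self-pair are skipped.
    """
    def resolve(name: str) -> str | None:
        cid = term.lookup(name)
        if cid is None:
            return None
        if term.concepts[cid].term_type is TermType.CLINICAL_DRUG:
            return None
        return term.to_ingredient(cid)

    objects = [i for i in (resolve(n) for n in group.object_members) if i]
    precipitants = [i for i in (resolve(n) for n in group.precipitant_members) if i]
    return {
        canonical_pair(o, p) for o in objects for p in precipitants if o != p
    }


def coverage_of_reference(
    source: NormalizedDdiSet,
    groups: list[ReferenceGroup],
    term: Terminology,
) -> ReferenceCoverage:
    """Coverage of the reference groups by one source.

    A pair belonging to two groups counts in each group's row but only once
    in the totals (totals are computed on the deduplicated union).
    """
    all_pairs: set[CanonicalPair] = set()
    rows: list[GroupCoverage] = []
    for group in groups:
        pairs = _group_canonical_pairs(group, term)
        matched = len(pairs & source.pairs)
        rows.append(
            GroupCoverage(
                group_id=group.group_id,
                label=group.label,
                n_pairs=len(pairs),
                matched=matched,
                matched_pct=round_percent(matched, len(pairs)) if pairs else 0,
            )
        )
        all_pairs |= pairs
    total_matched = len(all_pairs & source.pairs)
    return ReferenceCoverage(
        groups=tuple(rows),
        total_pairs=len(all_pairs),
        total_matched=total_matched,
        total_pct=round_percent(total_matched, len(all_pairs)) if all_pairs else 0,
    )


def severity_stratified_coverage(
    a: NormalizedDdiSet, b: NormalizedDdiSet
) -> dict[Severity, int]:
    """Coverage of each severity stratum of ``a`` by ``b``.

    ``a`` must carry a severity for every pair.  Empty strata are omitted.
    """
    missing = a.pairs - set(a.severity_of)
    if missing:
        raise ValueError(f"{len(missing)} pairs lack a severity annotation")
    out: dict[Severity, int] = {}
    for severity in Severity:
        stratum = {p for p, s in a.severity_of.items() if s is severity}
        if not stratum:
            continue
        out[severity] = round_percent(len(stratum & b.pairs), len(stratum))
    return out
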