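"""Interaction screening of patient medication lists.

A prescription list is a set of co-prescribed clinical drugs for one
patient.  Screening proceeds as a pharmacist's checker would: drop topical
products (ingredient-level interaction knowledge refers to systemic
exposure), expand every unordered clinical-drug pair to all combinations
of the two products' ingredients (a combination product contributes each
of its ingredients), collapse self-pairs and within-list duplicates, and
match the resulting canonical ingredient pairs against one or more
normalized interaction sets, accumulating occurrence frequencies across
lists.

One list is one co-prescription event: a canonical pair occurring several
times inside a single list (e.g. via two combination products sharing an
ingredient) counts once for that list.  A list may carry a repeat weight,
in which case its pairs count that many occurrences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .normalization import CanonicalPair, NormalizedDdiSet, canonical_pair
from .terminology import RouteClass, Terminology, TermType


class ResolutionError(KeyError):
    pass


@dataclass(frozen=True)
class PrescriptionList:
    """Clinical drugs co-prescribed to one patient, with a repeat weight."""

    patient_id: str
    drugs: tuple[str, ...]
    weight: int = 1

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"patient {self.patient_id!r}: empty drug list")
        if self.weight < 1:
            raise ValueError(f"patient {self.patient_id!r}: weight must be >= 1")


@dataclass
class MatchStats:
    total: int = 0
    unique: int = 0


@dataclass
class ScreeningResult:
    total_pairs: int = 0
    unique_pairs: int = 0
    pair_frequency: Counter = field(default_factory=Counter)
    per_source_matches: dict[str, MatchStats] = field(default_factory=dict)
    both_sources: MatchStats = field(default_factory=MatchStats)
    matched_by: dict[CanonicalPair, frozenset[str]] = field(default_factory=dict)


def filter_systemic(
    plist: PrescriptionList, term: Terminology
) -> PrescriptionList | None:
    """Remove topical drugs, preserving order; ``None`` if nothing remains."""
    kept = []
    for cid in plist.drugs:
        concept = term.concepts.get(cid)
        if concept is None or concept.term_type is not TermType.CLINICAL_DRUG:
            raise ResolutionError(
                f"patient {plist.patient_id!r}: {cid!r} is not a known clinical drug"
            )
        if concept.route_class is not RouteClass.TOPICAL:
            kept.append(cid)
    if not kept:
        return None
    return PrescriptionList(plist.patient_id, tuple(kept), plist.weight)


def expand_to_ingredient_pairs(
    plist: PrescriptionList, term: Terminology
) -> set[CanonicalPair]:
    """All ingredient pairs induced by one (systemic-filtered) list.

    Every unordered pair of distinct clinical drugs contributes the cross
    product of the two drugs' ingredient sets; self-pairs are dropped and
    duplicates within the list collapse to one occurrence.
    """
    drugs = sorted(set(plist.drugs))
    pairs: set[CanonicalPair] = set()
    for i, d1 in enumerate(drugs):
        ing1 = term.ingredients_of(d1)
        for d2 in drugs[i + 1:]:
            for a in ing1:
                for b in term.ingredients_of(d2):
                    if a != b:
                        pairs.add(canonical_pair(a, b))
    return pairs


def screen(
    lists: Iterable[PrescriptionList],
    sources: list[NormalizedDdiSet],
    term: Terminology,
) -> ScreeningResult:
    """Stream prescription lists against the interaction sources.

    Occurrence totals weight each list by its repeat count; unique counts
    are over distinct canonical pairs.  The "both sources" row matches
    against the intersection of all sources' pair sets.  The result is
    invariant under reordering of the input stream.
    """
    result = ScreeningResult()
    freq = result.pair_frequency
    for plist in lists:
        filtered = filter_systemic(plist, term)
        if filtered is None:
            continue
        for pair in expand_to_ingredient_pairs(filtered, term):
            freq[pair] += filtered.weight

    result.total_pairs = sum(freq.values())
    result.unique_pairs = len(freq)

    source_names = [s.source.value for s in sources]
    for name, source in zip(source_names, sources):
        matched = {p: n for p, n in freq.items() if p in source.pairs}
        result.per_source_matches[name] = MatchStats(
            total=sum(matched.values()), unique=len(matched)
        )
        for p in matched:
            result.matched_by[p] = result.matched_by.get(p, frozenset()) | {name}
    if sources:
        common = set.intersection(*(s.pairs for s in sources))
        matched_both = {p: n for p, n in freq.items() if p in common}
        result.both_sources = MatchStats(
            total=sum(matched_both.values()), unique=len(matched_both)
        )
    return result


def top_pairs(result: ScreeningResult, k: int) -> list[tuple[CanonicalPair, int, frozenset[str]]]:
    """The k most frequent matched pairs with their matching sources.

    Sorted by occurrence count descending; ties broken by the canonical
    pair identifiers.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rows = [
        (pair, result.pair_frequency[pair], sources)
        for pair, sources in result.matched_by.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows[:k]


def read_prescriptions(
    path: str | Path, term: Terminology
) -> list[PrescriptionList]:
    """Read prescription lists from CSV.

    Columns: ``patient_id``; ``drug_id`` or ``drug_name`` (names resolved
    through the terminology); optional ``count`` (repeat weight of the
    patient's list, default 1, constant within a patient).  One row per
    prescribed drug; rows grouped by patient.
    """
    df = pd.read_csv(path, dtype=str)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing patient_id column")
    if "drug_id" in df.columns:
        ids = df["drug_id"]
    elif "drug_name" in df.columns:
        def resolve(name: str) -> str:
            cid = term.lookup(name)
            if cid is None:
                raise ResolutionError(f"{path}: unknown drug name {name!r}")
            return cid
        ids = df["drug_name"].map(resolve)
    else:
        raise ValueError(f"{path}: need a drug_id or drug_name column")
    df = df.assign(_cid=ids)
    counts = (
        df["count"].fillna("1").astype(int) if "count" in df.columns
        else pd.Series(1, index=df.index)
    )
    df = df.assign(_count=counts)

    lists: list[PrescriptionList] = []
    for patient_id, grp in df.groupby("patient_id", sort=True):
        weights = set(grp["_count"])
        if len(weights) > 1:
            raise ValueError(
                f"{path}: patient {patient_id!r} has non-uniform repeat counts"
            )
        lists.append(
            PrescriptionList(
                patient_id=str(patient_id),
                drugs=tuple(grp["_cid"]),
                weight=weights.pop(),
            )
        )
    return lists
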