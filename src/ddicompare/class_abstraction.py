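"""Abstraction of ingredient-level interactions to ATC class pairs.

To look for systematic coverage differences between two interaction
sources, each ingredient pair is lifted to the fourth-level ATC classes of
its members.  Pairs with a member outside ATC are excluded (and counted).
An ingredient carrying several fourth-level classes fans out to every
class combination, so one interaction can appear under multiple class
pairs; class pairs are unordered and a pair may be same-class, keyed
(c, c).  Per class pair, the overlap between the two sources is summarized
with the Jaccard score |A ∩ B| / |A ∪ B|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .normalization import CanonicalPair, NormalizedDdiSet
from .terminology import Terminology

ClassPair = tuple[str, str]


def class_pair(a: str, b: str) -> ClassPair:
    """Unordered ATC class pair; members may coincide."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ClassPairMap:
    """Interactions of one source, grouped by ATC class pair."""

    by_class_pair: dict[ClassPair, set[CanonicalPair]] = field(default_factory=dict)
    excluded_ddis: int = 0  # pairs with a member outside ATC


@dataclass(frozen=True)
class ClassPairStats:
    class_a: str
    class_b: str
    total: int
    only_a: int
    only_b: int
    shared: int
    jaccard: float


@dataclass(frozen=True)
class ClassProfile:
    atc_code: str
    atc_name: str
    ddi_count: int
    drug_count: int


def abstract_to_class_pairs(
    s: NormalizedDdiSet, term: Terminology
) -> ClassPairMap:
    """Group a source's interactions by the ATC class pairs they instantiate.

    An interaction is excluded when either ingredient has no fourth-level
    ATC class; multi-class ingredients contribute the interaction to every
    class-pair combination.
    """
    out = ClassPairMap()
    for pair in s.pairs:
        classes_low = term.atc_classes(pair.low_id)
        classes_high = term.atc_classes(pair.high_id)
        if not classes_low or not classes_high:
            out.excluded_ddis += 1
            continue
        for ca in classes_low:
            for cb in classes_high:
                out.by_class_pair.setdefault(class_pair(ca, cb), set()).add(pair)
    return out


def class_profiles(s: NormalizedDdiSet, term: Terminology) -> list[ClassProfile]:
    """Per-class interaction and member-drug counts for one source.

    ``ddi_count`` is the number of distinct interactions with at least one
    member in the class; ``drug_count`` the distinct member ingredients of
    the class occurring in those interactions.  Sorted by ddi_count
    descending, then class code.
    """
    ddis: dict[str, set[CanonicalPair]] = {}
    drugs: dict[str, set[str]] = {}
    for pair in s.pairs:
        for ingredient in pair:
            for code in term.atc_classes(ingredient):
                ddis.setdefault(code, set()).add(pair)
                drugs.setdefault(code, set()).add(ingredient)
    profiles = [
        ClassProfile(
            atc_code=code,
            atc_name=term.atc_names.get(code, ""),
            ddi_count=len(pairs),
            drug_count=len(drugs[code]),
        )
        for code, pairs in ddis.items()
    ]
    profiles.sort(key=lambda p: (-p.ddi_count, p.atc_code))
    return profiles


def class_pair_jaccard(
    a_map: ClassPairMap | dict[ClassPair, set[CanonicalPair]],
    b_map: ClassPairMap | dict[ClassPair, set[CanonicalPair]],
) -> list[ClassPairStats]:
    """Per-class-pair overlap statistics between two sources.

    Emits one row per class pair present in either map, sorted by total
    interactions descending (ties by class codes).  ``jaccard`` is
    shared / (shared + only_a + only_b), carried at full precision.
    """
    a = a_map.by_class_pair if isinstance(a_map, ClassPairMap) else a_map
    b = b_map.by_class_pair if isinstance(b_map, ClassPairMap) else b_map
    rows: list[ClassPairStats] = []
    for key in set(a) | set(b):
        sa = a.get(key, set())
        sb = b.get(key, set())
        shared = len(sa & sb)
        only_a = len(sa) - shared
        only_b = len(sb) - shared
        total = shared + only_a + only_b
        rows.append(
            ClassPairStats(
                class_a=key[0],
                class_b=key[1],
                total=total,
                only_a=only_a,
                only_b=only_b,
                shared=shared,
                jaccard=shared / total if total else 0.0,
            )
        )
    rows.sort(key=lambda r: (-r.total, r.class_a, r.class_b))
    return rows
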