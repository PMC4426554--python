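"""Ingredient-level normalization of raw interaction lists.

Raw records name drugs free-form: base ingredients, salt/ester forms, or
occasionally dispensable products.  Normalization resolves every name in
the terminology (exact match, then normalized string match), collapses
salt forms to their base ingredient, folds each record into an unordered
canonical ingredient pair, and deduplicates.  Every discarded record is
counted, and the audit report satisfies a conservation equation::

    output_size = total_input - unmapped_ddis - collapsed_duplicates
                  - self_pairs_dropped - multi_ingredient_dropped

Records with an unresolvable name (including names that hit only obsolete
concepts) are discarded as unmapped.  Records resolving to clinical drugs
are dropped rather than expanded: interaction assertions live at the
ingredient level, and product-level expansion belongs to prescription
screening, not source normalization.  When duplicates merge with
conflicting severities the higher severity (critical over significant) is
kept.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .source_ingest import RawDdi, Severity, Source
from .terminology import Terminology, TermType


class SelfPairError(ValueError):
    pass


class CanonicalPair(NamedTuple):
    """Unordered ingredient pair, members in lexicographic id order."""

    low_id: str
    high_id: str


def canonical_pair(a: str, b: str) -> CanonicalPair:
    """Order an ingredient pair canonically; symmetric in its arguments."""
    if a == b:
        raise SelfPairError(f"self-pair {a!r}; filter self-interactions first")
    return CanonicalPair(a, b) if a < b else CanonicalPair(b, a)


@dataclass
class NormalizedDdiSet:
    """Deduplicated canonical ingredient pairs from one source."""

    source: Source
    pairs: set[CanonicalPair] = field(default_factory=set)
    severity_of: dict[CanonicalPair, Severity] = field(default_factory=dict)
    description_of: dict[CanonicalPair, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.severity_of, self.description_of):
            extra = set(mapping) - self.pairs
            if extra:
                raise ValueError(f"annotations for pairs not in the set: {extra}")


@dataclass(frozen=True)
class NormalizationReport:
    """Accounting of one normalization run; see the conservation equation."""

    total_input: int
    unmapped_ddis: int
    unmapped_drugs: int
    collapsed_duplicates: int
    self_pairs_dropped: int
    multi_ingredient_dropped: int
    output_size: int

    def __post_init__(self) -> None:
        expected = (
            self.total_input
            - self.unmapped_ddis
            - self.collapsed_duplicates
            - self.self_pairs_dropped
            - self.multi_ingredient_dropped
        )
        if self.output_size != expected:
            raise ValueError(
                f"report does not conserve records: output_size="
                f"{self.output_size}, expected {expected}"
            )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def normalize_ddi_list(
    raw: Iterable[RawDdi], term: Terminology
) -> tuple[NormalizedDdiSet, NormalizationReport]:
    """Normalize a single-source raw interaction list to ingredient pairs.

    Raises ``ValueError`` if the records do not all share one source tag.
    """
    raw = list(raw)
    sources = {r.source for r in raw}
    if len(sources) > 1:
        raise ValueError(f"mixed source tags in one normalization run: {sources}")
    source = sources.pop() if sources else Source.OTHER

    pairs: set[CanonicalPair] = set()
    severity_of: dict[CanonicalPair, Severity] = {}
    description_of: dict[CanonicalPair, str] = {}
    unmapped_names: set[str] = set()
    n_unmapped = n_dup = n_self = n_multi = 0

    for record in raw:
        ids = []
        missing = False
        for name in (record.drug_a_name, record.drug_b_name):
            cid = term.lookup(name)
            if cid is None:
                unmapped_names.add(name)
                missing = True
            else:
                ids.append(cid)
        if missing:
            n_unmapped += 1
            continue
        if any(term.concepts[c].term_type is TermType.CLINICAL_DRUG for c in ids):
            n_multi += 1
            continue
        a, b = (term.to_ingredient(c) for c in ids)
        if a == b:
            n_self += 1
            continue
        pair = canonical_pair(a, b)
        if pair in pairs:
            n_dup += 1
        else:
            pairs.add(pair)
        if record.severity is not None:
            prev = severity_of.get(pair)
            if prev is None or prev < record.severity:
                severity_of[pair] = record.severity
        if record.description is not None:
            # lexicographic min keeps the merge order-insensitive
            prev_desc = description_of.get(pair)
            if prev_desc is None or record.description < prev_desc:
                description_of[pair] = record.description

    report = NormalizationReport(
        total_input=len(raw),
        unmapped_ddis=n_unmapped,
        unmapped_drugs=len(unmapped_names),
        collapsed_duplicates=n_dup,
        self_pairs_dropped=n_self,
        multi_ingredient_dropped=n_multi,
        output_size=len(pairs),
    )
    return (
        NormalizedDdiSet(
            source=source,
            pairs=pairs,
            severity_of=severity_of,
            description_of=description_of,
        ),
        report,
    )


# -- serialization ----------------------------------------------------


def write_normalized_set(s: NormalizedDdiSet, path: str | Path) -> None:
    """Write a normalized set as TSV (low_id, high_id, severity, description)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["low_id", "high_id", "severity", "description"])
        for pair in sorted(s.pairs):
            sev = s.severity_of.get(pair)
            writer.writerow(
                [
                    pair.low_id,
                    pair.high_id,
                    sev.value.lower() if sev else "",
                    s.description_of.get(pair, ""),
                ]
            )


def read_normalized_set(path: str | Path, source: Source) -> NormalizedDdiSet:
    pairs: set[CanonicalPair] = set()
    severity_of: dict[CanonicalPair, Severity] = {}
    description_of: dict[CanonicalPair, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pair = CanonicalPair(row["low_id"], row["high_id"])
            pairs.add(pair)
            if row.get("severity"):
                severity_of[pair] = Severity(row["severity"].upper())
            if row.get("description"):
                description_of[pair] = row["description"]
    return NormalizedDdiSet(
        source=source, pairs=pairs, severity_of=severity_of,
        description_of=description_of,
    )
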