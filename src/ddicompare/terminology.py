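"""In-memory drug terminology modeled on RxNorm's ingredient network.

The terminology holds three kinds of concepts: *ingredients* (base active
moieties such as diltiazem), *precise ingredients* (salt or ester forms such
as diltiazem hydrochloride), and *clinical drugs* (dispensable products such
as "Lovastatin 20 MG Oral Tablet", possibly multi-ingredient).  Links connect
precise ingredients to their base ingredient and clinical drugs to their
ingredient sets; fourth-level ATC class codes hang off ingredients.

Concepts are loaded from three TSV files (see :func:`load_terminology`) and
looked up by name with an exact match first, then a normalized match
(case-folded, punctuation-stripped).  Name resolution of obsolete concepts
is suppressed so that downstream normalization discards records that
reference them.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path


class TermType(enum.Enum):
    INGREDIENT = "INGREDIENT"
    PRECISE_INGREDIENT = "PRECISE_INGREDIENT"
    CLINICAL_DRUG = "CLINICAL_DRUG"


class RouteClass(enum.Enum):
    SYSTEMIC = "SYSTEMIC"
    TOPICAL = "TOPICAL"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class TerminologyError(Exception):
    """Base class for terminology load/lookup failures."""


class ParseError(TerminologyError):
    """A file row could not be parsed; message names the file and line."""


class IntegrityError(TerminologyError):
    """Cross-references within the terminology bundle do not resolve."""


@dataclass(frozen=True)
class Concept:
    """One terminology entry (an RxCUI analogue with a preferred name)."""

    concept_id: str
    name: str
    term_type: TermType
    route_class: RouteClass = RouteClass.NOT_APPLICABLE
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise IntegrityError("concept_id must be non-empty")
        if (
            self.term_type is not TermType.CLINICAL_DRUG
            and self.route_class is not RouteClass.NOT_APPLICABLE
        ):
            raise IntegrityError(
                f"route_class is only meaningful on clinical drugs "
                f"({self.concept_id!r} is {self.term_type.value})"
            )


# Characters the normalized string match strips (dosage punctuation, salts
# written with apostrophes, slashes in combination names, ...).
_PUNCT = re.compile(r"[,.;:'’\"()/\-]")
_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Normalize a drug name for matching.

    Case-folds, strips surrounding whitespace, removes the punctuation
    characters ``,.;:'"()/-`` and collapses internal whitespace runs to a
    single space.  Idempotent; the empty string maps to itself.
    """
    out = _PUNCT.sub("", raw.casefold())
    return _WS.sub(" ", out).strip()


@dataclass
class Terminology:
    """Concept store plus name index and link maps.

    Invariants (enforced by :meth:`validate`, called on load):

    * every id in a link map resolves to a stored concept of the required
      term type;
    * every precise ingredient has a base ingredient;
    * every clinical drug maps to a non-empty ingredient set;
    * normalized names are unique across non-obsolete concepts.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    name_index: dict[str, str] = field(default_factory=dict)
    exact_index: dict[str, str] = field(default_factory=dict)
    precise_to_ingredient: dict[str, str] = field(default_factory=dict)
    drug_to_ingredients: dict[str, frozenset[str]] = field(default_factory=dict)
    atc_assignments: dict[str, frozenset[str]] = field(default_factory=dict)
    atc_names: dict[str, str] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise IntegrityError(f"duplicate concept_id {concept.concept_id!r}")
        self.concepts[concept.concept_id] = concept
        if concept.obsolete:
            return
        norm = normalize_name(concept.name)
        if norm in self.name_index:
            other = self.name_index[norm]
            raise IntegrityError(
                f"names of {concept.concept_id!r} and {other!r} both "
                f"normalize to {norm!r}"
            )
        self.name_index[norm] = concept.concept_id
        self.exact_index[concept.name] = concept.concept_id

    def validate(self) -> None:
        dangling: list[str] = []
        for pid, iid in self.precise_to_ingredient.items():
            if self._term_type(pid) is not TermType.PRECISE_INGREDIENT:
                dangling.append(pid)
            if self._term_type(iid) is not TermType.INGREDIENT:
                dangling.append(iid)
        for did, iids in self.drug_to_ingredients.items():
            if self._term_type(did) is not TermType.CLINICAL_DRUG:
                dangling.append(did)
            if not iids:
                raise IntegrityError(f"clinical drug {did!r} has no ingredients")
            dangling.extend(i for i in iids if self._term_type(i) is not TermType.INGREDIENT)
        for iid in self.atc_assignments:
            if self._term_type(iid) is not TermType.INGREDIENT:
                dangling.append(iid)
        if dangling:
            raise IntegrityError(
                "link ids do not resolve to concepts of the required term "
                "type: " + ", ".join(sorted(set(dangling)))
            )
        for cid, c in self.concepts.items():
            if c.term_type is TermType.PRECISE_INGREDIENT and cid not in self.precise_to_ingredient:
                raise IntegrityError(f"precise ingredient {cid!r} has no base ingredient link")
            if c.term_type is TermType.CLINICAL_DRUG and cid not in self.drug_to_ingredients:
                raise IntegrityError(f"clinical drug {cid!r} has no ingredient links")

    def _term_type(self, cid: str) -> TermType | None:
        c = self.concepts.get(cid)
        return c.term_type if c else None

    # -- queries ------------------------------------------------------

    def lookup(self, name: str) -> str | None:
        """Resolve a drug name to a concept id, or ``None``.

        An exact match on the preferred name is tried first, then a
        normalized match.  Obsolete concepts never resolve.
        """
        cid = self.exact_index.get(name)
        if cid is None:
            cid = self.name_index.get(normalize_name(name))
        return cid

    def to_ingredient(self, cid: str) -> str:
        """Collapse a (precise) ingredient id to its base ingredient id."""
        concept = self.concepts.get(cid)
        if concept is None:
            raise TypeError(f"unknown concept id {cid!r}")
        if concept.term_type is TermType.INGREDIENT:
            return cid
        if concept.term_type is TermType.PRECISE_INGREDIENT:
            return self.precise_to_ingredient[cid]
        raise TypeError(
            f"{cid!r} is a clinical drug; use ingredients_of() to expand it"
        )

    def ingredients_of(self, cid: str) -> frozenset[str]:
        """Ingredient set of a clinical drug (size >= 1)."""
        concept = self.concepts.get(cid)
        if concept is None or concept.term_type is not TermType.CLINICAL_DRUG:
            raise TypeError(f"{cid!r} is not a clinical drug")
        return self.drug_to_ingredients[cid]

    def atc_classes(self, ingredient_id: str) -> frozenset[str]:
        """Fourth-level ATC codes of an ingredient; empty if outside ATC."""
        concept = self.concepts.get(ingredient_id)
        if concept is None or concept.term_type is not TermType.INGREDIENT:
            raise TypeError(f"{ingredient_id!r} is not an ingredient")
        return self.atc_assignments.get(ingredient_id, frozenset())


# -- loading ----------------------------------------------------------


def _read_tsv(path: Path, required: list[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise ParseError(
                f"{path}: expected header with columns {', '.join(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) in (None, "") for c in required):
                raise ParseError(f"{path}:{lineno}: missing required field")
            yield lineno, row


def load_terminology(
    concept_file: str | Path,
    relation_file: str | Path,
    atc_file: str | Path,
) -> Terminology:
    """Load a terminology bundle from its three TSV files.

    ``concepts.tsv``  columns: concept_id, name, term_type, route_class,
    obsolete (0/1).  ``relations.tsv``  columns: rel_type
    (``has_ingredient_base`` for salt->base, ``has_ingredient`` for
    drug->ingredient), source_id, target_id.  ``atc.tsv``  columns:
    ingredient_id, atc_code, atc_name.

    Raises :class:`ParseError` on malformed rows (naming file and line) and
    :class:`IntegrityError` on dangling references or normalized-name
    collisions.
    """
    term = Terminology()
    concept_file, relation_file, atc_file = (
        Path(concept_file), Path(relation_file), Path(atc_file),
    )

    for lineno, row in _read_tsv(
        concept_file, ["concept_id", "name", "term_type", "route_class", "obsolete"]
    ):
        try:
            concept = Concept(
                concept_id=row["concept_id"],
                name=row["name"],
                term_type=TermType(row["term_type"]),
                route_class=RouteClass(row["route_class"]),
                obsolete=row["obsolete"] == "1",
            )
        except ValueError as exc:
            raise ParseError(f"{concept_file}:{lineno}: {exc}") from exc
        term.add_concept(concept)

    drug_links: dict[str, set[str]] = {}
    for lineno, row in _read_tsv(relation_file, ["rel_type", "source_id", "target_id"]):
        rel, src, tgt = row["rel_type"], row["source_id"], row["target_id"]
        if rel == "has_ingredient_base":
            term.precise_to_ingredient[src] = tgt
        elif rel == "has_ingredient":
            drug_links.setdefault(src, set()).add(tgt)
        else:
            raise ParseError(f"{relation_file}:{lineno}: unknown rel_type {rel!r}")
    term.drug_to_ingredients = {d: frozenset(s) for d, s in drug_links.items()}

    atc: dict[str, set[str]] = {}
    atc_names: dict[str, str] = {}
    for lineno, row in _read_tsv(atc_file, ["ingredient_id", "atc_code", "atc_name"]):
        atc.setdefault(row["ingredient_id"], set()).add(row["atc_code"])
        atc_names[row["atc_code"]] = row["atc_name"]
    term.atc_assignments = {i: frozenset(s) for i, s in atc.items()}
    term.atc_names = atc_names

    term.validate()
    return term
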