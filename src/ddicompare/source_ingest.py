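"""Readers for raw drug-drug interaction lists.

Three source shapes are supported:

* a DrugBank-style XML dialect — drug records carrying interaction lists
  with free-text descriptions and no severity;
* an NDF-RT-style TSV — one drug-name pair per row with a two-level
  severity annotation (``significant`` or ``critical``);
* expert-curated reference groups (YAML) — blocks of object drugs and
  precipitant drugs whose cross-product defines the reference interactions.

All readers produce :class:`RawDdi` records: name-level, unnormalized, one
per asserted interaction.  Writers are provided so that a round trip
(write then read) reproduces the record list exactly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import csv
import yaml
from lxml import etree

from .terminology import Terminology, TermType, normalize_name


class Source(enum.Enum):
    NDFRT = "NDFRT"
    DRUGBANK = "DRUGBANK"
    REFERENCE = "REFERENCE"
    OTHER = "OTHER"


class Severity(enum.Enum):
    SIGNIFICANT = "SIGNIFICANT"
    CRITICAL = "CRITICAL"

    def __lt__(self, other: "Severity") -> bool:  # CRITICAL outranks
        order = [Severity.SIGNIFICANT, Severity.CRITICAL]
        return order.index(self) < order.index(other)


class IngestError(Exception):
    pass


@dataclass(frozen=True)
class RawDdi:
    """One asserted interaction, as named by its source."""

    source: Source
    drug_a_name: str
    drug_b_name: str
    severity: Severity | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if self.severity is not None and self.source is not Source.NDFRT:
            raise IngestError(
                f"severity annotation is only defined for NDF-RT records, "
                f"not {self.source.value}"
            )


@dataclass(frozen=True)
class ReferenceGroup:
    """A reference-set block: every object member interacts with every
    precipitant member."""

    group_id: int
    label: str
    object_members: tuple[str, ...]
    precipitant_members: tuple[str, ...]

    def __post_init__(self) -> None:
        for side, members in (
            ("object", self.object_members),
            ("precipitant", self.precipitant_members),
        ):
            if not members:
                raise IngestError(f"group {self.group_id}: empty {side} member list")
            if len(set(members)) != len(members):
                raise IngestError(f"group {self.group_id}: duplicate {side} members")


# -- DrugBank-style XML ----------------------------------------------


def read_drugbank_xml(path: str | Path) -> list[RawDdi]:
    """Extract interaction pairs from a DrugBank-style XML file.

    Each ``<drug-interaction>`` element yields one record pairing the
    enclosing drug record's name with the partner name, carrying the
    free-text description.  All other elements are ignored.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IngestError(f"{path}: malformed XML: {exc}") from exc

    declared = {
        d.findtext("drugbank-id"): d.findtext("name")
        for d in tree.getroot().iterfind("drug")
    }
    records: list[RawDdi] = []
    for drug in tree.getroot().iterfind("drug"):
        drug_name = drug.findtext("name")
        for inter in drug.iterfind("drug-interactions/drug-interaction"):
            partner_id = inter.findtext("drugbank-id")
            partner_name = inter.findtext("name")
            if partner_id is not None and partner_id not in declared:
                warnings.warn(
                    f"{path}: interaction of {drug_name!r} references "
                    f"undeclared partner id {partner_id!r}; keeping literal "
                    f"name {partner_name!r}",
                    stacklevel=2,
                )
            records.append(
                RawDdi(
                    source=Source.DRUGBANK,
                    drug_a_name=drug_name,
                    drug_b_name=partner_name,
                    description=inter.findtext("description"),
                )
            )
    return records


def write_drugbank_xml(records: list[RawDdi], path: str | Path) -> None:
    """Serialize records back to the XML dialect (round-trip support)."""
    by_drug: dict[str, list[RawDdi]] = {}
    for r in records:
        by_drug.setdefault(r.drug_a_name, []).append(r)
    root = etree.Element("drugbank")
    ids = {name: f"DB{i:05d}" for i, name in enumerate(
        sorted({r.drug_a_name for r in records} | {r.drug_b_name for r in records}), 1
    )}
    for name, recs in by_drug.items():
        drug = etree.SubElement(root, "drug")
        etree.SubElement(drug, "drugbank-id").text = ids[name]
        etree.SubElement(drug, "name").text = name
        inters = etree.SubElement(drug, "drug-interactions")
        for r in recs:
            el = etree.SubElement(inters, "drug-interaction")
            etree.SubElement(el, "drugbank-id").text = ids[r.drug_b_name]
            etree.SubElement(el, "name").text = r.drug_b_name
            if r.description is not None:
                etree.SubElement(el, "description").text = r.description
    # declare partners that have no record block of their own
    for name, cid in sorted(ids.items(), key=lambda kv: kv[1]):
        if name not in by_drug:
            drug = etree.SubElement(root, "drug")
            etree.SubElement(drug, "drugbank-id").text = cid
            etree.SubElement(drug, "name").text = name
            etree.SubElement(drug, "drug-interactions")
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# -- NDF-RT-style TSV ------------------------------------------------


def read_ndfrt_records(path: str | Path) -> list[RawDdi]:
    """Read severity-annotated interaction pairs from a TSV file.

    Columns: ``drug_a``, ``drug_b``, ``severity`` (``significant`` or
    ``critical``, case-insensitive).  Any other severity token is an error.
    """
    records: list[RawDdi] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        for col in ("drug_a", "drug_b", "severity"):
            if col not in cols:
                raise IngestError(f"{path}: missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            token = (row["severity"] or "").strip().casefold()
            try:
                severity = Severity(token.upper())
            except ValueError:
                raise IngestError(
                    f"{path}:{lineno}: unknown severity {row['severity']!r} "
                    f"(expected significant or critical)"
                ) from None
            records.append(
                RawDdi(
                    source=Source.NDFRT,
                    drug_a_name=row["drug_a"],
                    drug_b_name=row["drug_b"],
                    severity=severity,
                )
            )
    return records


def write_ndfrt_records(records: list[RawDdi], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_a", "drug_b", "severity"])
        for r in records:
            writer.writerow(
                [r.drug_a_name, r.drug_b_name, r.severity.value.lower()]
            )


# -- reference groups ------------------------------------------------


def read_reference_groups(path: str | Path) -> list[ReferenceGroup]:
    """Read reference-group definitions from YAML."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return _groups_from_obj(data)


def _groups_from_obj(data) -> list[ReferenceGroup]:
    groups = []
    for entry in data:
        groups.append(
            ReferenceGroup(
                group_id=int(entry["group_id"]),
                label=str(entry["label"]),
                object_members=tuple(entry["objects"]),
                precipitant_members=tuple(entry["precipitants"]),
            )
        )
    return groups


def packaged_reference_groups() -> list[ReferenceGroup]:
    """The expert-curated high-severity reference groups shipped with the
    package (12 blocks expanding to 360 interacting pairs of 86 drugs)."""
    from importlib.resources import files

    text = files("ddicompare.data").joinpath("reference_groups.yaml").read_text("utf-8")
    return _groups_from_obj(yaml.safe_load(text))


def build_reference_set(
    groups: list[ReferenceGroup],
    term: Terminology | None = None,
) -> list[RawDdi]:
    """Expand reference groups into a flat interaction list.

    For each group the full object x precipitant cross-product is emitted.
    Pairs whose two members normalize to the same name are skipped, and
    pairs duplicated across groups are emitted once (pairs are unordered).
    When a terminology is supplied, pairs with a member resolving to a
    multi-ingredient clinical drug are dropped with a warning, since such
    drugs are not consistently represented across interaction sources.
    """
    seen: set[frozenset[str]] = set()
    out: list[RawDdi] = []
    for group in groups:
        for obj in group.object_members:
            for prec in group.precipitant_members:
                a, b = normalize_name(obj), normalize_name(prec)
                if a == b:
                    continue
                key = frozenset((a, b))
                if key in seen:
                    continue
                seen.add(key)
                if term is not None and _is_multi_ingredient(term, obj, prec):
                    warnings.warn(
                        f"reference pair ({obj!r}, {prec!r}) involves a "
                        f"multi-ingredient drug; dropped",
                        stacklevel=2,
                    )
                    continue
                out.append(
                    RawDdi(source=Source.REFERENCE, drug_a_name=obj, drug_b_name=prec)
                )
    return out


def _is_multi_ingredient(term: Terminology, *names: str) -> bool:
    for name in names:
        cid = term.lookup(name)
        if cid is None:
            continue
        concept = term.concepts[cid]
        if (
            concept.term_type is TermType.CLINICAL_DRUG
            and len(term.ingredients_of(cid)) > 1
        ):
            return True
    return False
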