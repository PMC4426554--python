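"""Synthetic terminology, interaction-source and prescription generator.

Every pipeline stage is exercised against data with known ground truth:
a terminology with salt forms and combination products, two interaction
sources with a planted pair overlap and salt-form name noise, reference
groups, and patient prescription lists with known pair frequencies.  The
generator writes exactly the file dialects the ingest modules read and
returns a :class:`GroundTruthLedger` recording what was planted, so
recovery tests can be exact: normalization and comparison are
deterministic set algebra, and any mismatch with the ledger is a bug, not
sampling error.

Default dimensions emulate the structure of real interaction sources at
desk scale: two sources of several hundred interactions with a 25-30%
overlap, roughly a third of source-A interactions labeled critical, an
appreciable share of drug names appearing as salt forms, combination
products, topical products, and a minority of ingredients outside ATC.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import csv
import yaml

from .normalization import CanonicalPair, canonical_pair
from .source_ingest import (
    RawDdi,
    Severity,
    Source,
    write_drugbank_xml,
    write_ndfrt_records,
)


class ConfigError(ValueError):
    pass


_SYLLABLES = [
    "al", "bex", "cal", "dor", "eze", "fen", "gli", "hex", "ib", "jan",
    "kel", "lor", "mab", "nex", "ol", "pra", "quin", "rov", "sta", "tin",
    "ul", "vex", "wim", "xan", "yol", "zor",
]
_SALT_WORDS = [
    "hydrochloride", "sulfate", "sodium", "acetate", "bisulfate",
    "chloride", "maleate", "tartrate",
]


def ingredient_id(i: int) -> str:
    """Identifier of the i-th generated ingredient (1-based)."""
    return f"ING{i:04d}"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic bundle; all rates are fractions in [0, 1]."""

    seed: int = 0
    n_ingredients: int = 300
    salt_rate: float = 0.3            # ingredients given >=1 salt form
    multi_ingredient_rate: float = 0.2  # clinical drugs with 2 ingredients
    topical_rate: float = 0.15        # clinical drugs labeled TOPICAL
    n_atc_classes: int = 25
    classes_per_ingredient: int = 1
    atc_missing_rate: float = 0.12    # ingredients outside ATC
    size_a: int = 500                 # normalized interactions in source A
    size_b: int = 600                 # ... in source B
    planted_overlap: int = 150        # |A ∩ B|
    salt_noise_rate: float = 0.2      # raw names emitted as salt forms
    unmapped_rate: float = 0.05       # extra records with unknown names
    critical_fraction: float = 0.33   # source-A severity mix
    n_patients: int = 200
    list_length_mean: float = 4.0
    planted_pairs: tuple[tuple[tuple[str, str], int], ...] = ()

    def validate(self) -> None:
        rates = {
            "salt_rate": self.salt_rate,
            "multi_ingredient_rate": self.multi_ingredient_rate,
            "topical_rate": self.topical_rate,
            "atc_missing_rate": self.atc_missing_rate,
            "salt_noise_rate": self.salt_noise_rate,
            "unmapped_rate": self.unmapped_rate,
            "critical_fraction": self.critical_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.planted_overlap > min(self.size_a, self.size_b):
            raise ConfigError("planted_overlap exceeds a source size")
        n_pairs_available = self.n_ingredients * (self.n_ingredients - 1) // 2
        needed = self.size_a + self.size_b - self.planted_overlap
        if needed > n_pairs_available:
            raise ConfigError(
                f"{needed} distinct interaction pairs requested but only "
                f"{n_pairs_available} exist over {self.n_ingredients} ingredients"
            )
        if self.list_length_mean < 1:
            raise ConfigError("list_length_mean must be >= 1")
        valid_ids = {ingredient_id(i) for i in range(1, self.n_ingredients + 1)}
        for (low, high), freq in self.planted_pairs:
            if low >= high:
                raise ConfigError(f"planted pair ({low}, {high}) not canonical")
            if low not in valid_ids or high not in valid_ids:
                raise ConfigError(f"planted pair ({low}, {high}) outside terminology")
            if freq < 1 or freq > self.n_patients:
                raise ConfigError(f"planted frequency {freq} infeasible")


@dataclass
class GroundTruthLedger:
    """What the generator planted, for exact recovery checks."""

    true_pairs_a: set[CanonicalPair] = field(default_factory=set)
    true_pairs_b: set[CanonicalPair] = field(default_factory=set)
    true_overlap: int = 0
    salt_redundant_records: dict[str, int] = field(default_factory=dict)
    unmapped_records: dict[str, int] = field(default_factory=dict)
    severity_of: dict[CanonicalPair, str] = field(default_factory=dict)
    pair_frequencies: dict[CanonicalPair, int] = field(default_factory=dict)
    planted_match_totals: dict[str, int] = field(default_factory=dict)
    unique_matches: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc_pairs(pairs):
            return sorted([p.low_id, p.high_id] for p in pairs)

        payload = {
            "true_pairs_a": enc_pairs(self.true_pairs_a),
            "true_pairs_b": enc_pairs(self.true_pairs_b),
            "true_overlap": self.true_overlap,
            "salt_redundant_records": self.salt_redundant_records,
            "unmapped_records": self.unmapped_records,
            "severity_of": {f"{p.low_id}|{p.high_id}": s for p, s in sorted(self.severity_of.items())},
            "pair_frequencies": {f"{p.low_id}|{p.high_id}": n for p, n in sorted(self.pair_frequencies.items())},
            "planted_match_totals": self.planted_match_totals,
            "unique_matches": self.unique_matches,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticBundle:
    """File paths of one generated bundle plus its ground truth."""

    concepts: Path
    relations: Path
    atc: Path
    ndfrt: Path
    drugbank: Path
    reference_groups: Path
    prescriptions: Path
    ledger_path: Path
    ledger: GroundTruthLedger


def _make_names(rng: random.Random, n: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        k = rng.randint(2, 4)
        name = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        if name in seen:
            continue
        seen.add(name)
        names.append(name)
    return names


def generate_bundle(cfg: GeneratorConfig, outdir: str | Path) -> SyntheticBundle:
    """Write a complete synthetic bundle to ``outdir``.

    Deterministic in ``cfg.seed``: the same config writes byte-identical
    files on every run.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cfg.seed)
    ledger = GroundTruthLedger()

    # --- ingredients, salts, ATC ------------------------------------
    ing_names = _make_names(rng, cfg.n_ingredients)
    ingredients = [ingredient_id(i) for i in range(1, cfg.n_ingredients + 1)]
    name_of = dict(zip(ingredients, ing_names))

    salt_of: dict[str, list[tuple[str, str]]] = {}  # ing -> [(salt_id, salt_name)]
    concept_rows: list[list[str]] = []
    relation_rows: list[list[str]] = []
    for iid in ingredients:
        concept_rows.append([iid, name_of[iid], "INGREDIENT", "NOT_APPLICABLE", "0"])
        if rng.random() < cfg.salt_rate:
            salt_id = iid.replace("ING", "PIN")
            salt_name = f"{name_of[iid]} {rng.choice(_SALT_WORDS)}"
            concept_rows.append(
                [salt_id, salt_name, "PRECISE_INGREDIENT", "NOT_APPLICABLE", "0"]
            )
            relation_rows.append(["has_ingredient_base", salt_id, iid])
            salt_of[iid] = [(salt_id, salt_name)]

    atc_codes = [
        f"{chr(ord('A') + i % 14)}{i % 10}{(i * 3) % 10}{chr(ord('A') + (i * 7) % 26)}{chr(ord('A') + (i * 11) % 26)}"
        for i in range(cfg.n_atc_classes)
    ]
    atc_rows: list[list[str]] = []
    for iid in ingredients:
        if rng.random() < cfg.atc_missing_rate:
            continue
        codes = rng.sample(atc_codes, min(cfg.classes_per_ingredient, len(atc_codes)))
        for code in sorted(codes):
            atc_rows.append([iid, code, f"class {code}"])

    # --- clinical drugs ---------------------------------------------
    # One single-ingredient product per ingredient; ingredients involved in
    # planted prescription pairs are forced systemic so the plant survives
    # the topical filter.
    planted_ings = {i for (pair, _) in cfg.planted_pairs for i in pair}
    drug_rows: list[tuple[str, str, str, tuple[str, ...]]] = []
    used_drug_names: set[str] = set()
    for idx, iid in enumerate(ingredients, start=1):
        did = f"CD{idx:04d}"
        strength = rng.choice([5, 10, 20, 25, 50, 100, 250])
        dname = f"{name_of[iid].capitalize()} {strength} MG Oral Tablet"
        topical = iid not in planted_ings and rng.random() < cfg.topical_rate
        if topical:
            dname = f"{name_of[iid].capitalize()} {strength} MG Topical Cream"
        used_drug_names.add(dname)
        drug_rows.append((did, dname, "TOPICAL" if topical else "SYSTEMIC", (iid,)))

    n_multi = round(
        cfg.multi_ingredient_rate * cfg.n_ingredients / max(1e-9, 1 - cfg.multi_ingredient_rate)
    )
    midx = cfg.n_ingredients
    while n_multi > 0:
        midx += 1
        a, b = rng.sample(ingredients, 2)
        s1 = rng.choice([5, 10, 25])
        s2 = rng.choice([50, 100, 250])
        dname = (
            f"{name_of[a].capitalize()} {s1} MG/{name_of[b].capitalize()} "
            f"{s2} MG Oral Tablet"
        )
        if dname in used_drug_names:
            continue
        used_drug_names.add(dname)
        topical = rng.random() < cfg.topical_rate
        if topical:
            dname = dname.replace("Oral Tablet", "Topical Cream")
        drug_rows.append(
            (f"CD{midx:04d}", dname, "TOPICAL" if topical else "SYSTEMIC",
             tuple(sorted((a, b))))
        )
        n_multi -= 1

    for did, dname, route, iids in drug_rows:
        concept_rows.append([did, dname, "CLINICAL_DRUG", route, "0"])
        for iid in iids:
            relation_rows.append(["has_ingredient", did, iid])
    drug_of_ing = {iids[0]: did for did, _, _, iids in drug_rows if len(iids) == 1}
    route_of = {did: route for did, _, route, _ in drug_rows}
    ings_of_drug = {did: iids for did, _, _, iids in drug_rows}

    # --- interaction pairs ------------------------------------------
    needed = cfg.size_a + cfg.size_b - cfg.planted_overlap
    pair_pool: set[CanonicalPair] = set()
    while len(pair_pool) < needed:
        a, b = rng.sample(ingredients, 2)
        pair_pool.add(canonical_pair(a, b))
    pool = sorted(pair_pool)
    rng.shuffle(pool)
    shared = pool[: cfg.planted_overlap]
    a_only = pool[cfg.planted_overlap: cfg.size_a]
    b_only = pool[cfg.size_a:]
    ledger.true_pairs_a = set(shared) | set(a_only)
    ledger.true_pairs_b = set(shared) | set(b_only)
    ledger.true_overlap = cfg.planted_overlap

    for pair in sorted(ledger.true_pairs_a):
        sev = "CRITICAL" if rng.random() < cfg.critical_fraction else "SIGNIFICANT"
        ledger.severity_of[pair] = sev

    def emit_name(iid: str) -> str:
        if iid in salt_of and rng.random() < cfg.salt_noise_rate:
            return salt_of[iid][0][1]
        return name_of[iid]

    def raw_records(pairs: list[CanonicalPair], source: Source) -> list[RawDdi]:
        records: list[RawDdi] = []
        n_dup = 0
        for pair in pairs:
            sev = (
                Severity(ledger.severity_of[pair]) if source is Source.NDFRT else None
            )
            desc = (
                f"Interaction between {name_of[pair.low_id]} and "
                f"{name_of[pair.high_id]}."
                if source is Source.DRUGBANK
                else None
            )
            records.append(
                RawDdi(source, emit_name(pair.low_id), emit_name(pair.high_id),
                       severity=sev, description=desc)
            )
            # salt-form redundancy: the same interaction re-asserted under a
            # salt name, which normalization must collapse
            salted = [i for i in pair if i in salt_of]
            if salted and rng.random() < cfg.salt_noise_rate / 2:
                m = rng.choice(salted)
                names = {
                    pair.low_id: name_of[pair.low_id],
                    pair.high_id: name_of[pair.high_id],
                }
                names[m] = salt_of[m][0][1]
                records.append(
                    RawDdi(source, names[pair.low_id], names[pair.high_id],
                           severity=sev, description=desc)
                )
                n_dup += 1
        n_unmapped = 0
        for k in range(int(round(cfg.unmapped_rate * len(pairs)))):
            fake = f"zz unknown {source.value.lower()} {k}"
            partner = name_of[rng.choice(ingredients)]
            sev = Severity.SIGNIFICANT if source is Source.NDFRT else None
            records.append(RawDdi(source, fake, partner, severity=sev))
            n_unmapped += 1
        ledger.salt_redundant_records[source.value] = n_dup
        ledger.unmapped_records[source.value] = n_unmapped
        rng.shuffle(records)
        return records

    records_a = raw_records(sorted(ledger.true_pairs_a), Source.NDFRT)
    records_b = raw_records(sorted(ledger.true_pairs_b), Source.DRUGBANK)

    # --- reference groups -------------------------------------------
    ref_groups = []
    pool_names = [name_of[i] for i in ingredients]
    cursor = 0
    for gid in range(1, 4):
        n_obj = rng.randint(1, 3)
        n_prec = rng.randint(2, 5)
        if cursor + n_obj + n_prec > len(pool_names):
            break
        members = pool_names[cursor: cursor + n_obj + n_prec]
        cursor += n_obj + n_prec
        ref_groups.append(
            {
                "group_id": gid,
                "label": f"synthetic group {gid}",
                "objects": members[:n_obj],
                "precipitants": members[n_obj:],
            }
        )

    # --- prescriptions ----------------------------------------------
    systemic_drugs = sorted(d for d, r in route_of.items() if r == "SYSTEMIC")
    all_drugs = sorted(route_of)
    p_stop = 1.0 / cfg.list_length_mean
    patients: dict[str, set[str]] = {}
    for n in range(1, cfg.n_patients + 1):
        pid = f"P{n:05d}"
        length = 1
        while rng.random() > p_stop and length < 10 * cfg.list_length_mean:
            length += 1
        patients[pid] = set(rng.sample(all_drugs, min(length, len(all_drugs))))
    patient_ids = sorted(patients)
    for (low, high), freq in cfg.planted_pairs:
        targets = rng.sample(patient_ids, freq)
        for pid in targets:
            patients[pid] |= {drug_of_ing[low], drug_of_ing[high]}

    # ground-truth recount of ingredient-pair frequencies (independent
    # nested-loop expansion over the generator's own link tables)
    freq_counter: dict[CanonicalPair, int] = {}
    for pid in patient_ids:
        drugs = [d for d in sorted(patients[pid]) if route_of[d] == "SYSTEMIC"]
        pairs_here: set[CanonicalPair] = set()
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                for x in ings_of_drug[drugs[i]]:
                    for y in ings_of_drug[drugs[j]]:
                        if x != y:
                            pairs_here.add(canonical_pair(x, y))
        for pair in pairs_here:
            freq_counter[pair] = freq_counter.get(pair, 0) + 1
    ledger.pair_frequencies = freq_counter
    both = ledger.true_pairs_a & ledger.true_pairs_b
    for label, pairs in (
        ("NDFRT", ledger.true_pairs_a),
        ("DRUGBANK", ledger.true_pairs_b),
        ("BOTH", both),
    ):
        matched = {p: n for p, n in freq_counter.items() if p in pairs}
        ledger.planted_match_totals[label] = sum(matched.values())
        ledger.unique_matches[label] = len(matched)

    # --- write files -------------------------------------------------
    def write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    paths = SyntheticBundle(
        concepts=outdir / "concepts.tsv",
        relations=outdir / "relations.tsv",
        atc=outdir / "atc.tsv",
        ndfrt=outdir / "ndfrt.tsv",
        drugbank=outdir / "drugbank.xml",
        reference_groups=outdir / "reference_groups.yaml",
        prescriptions=outdir / "prescriptions.csv",
        ledger_path=outdir / "ledger.json",
        ledger=ledger,
    )
    write_tsv(paths.concepts, ["concept_id", "name", "term_type", "route_class", "obsolete"], concept_rows)
    write_tsv(paths.relations, ["rel_type", "source_id", "target_id"], relation_rows)
    write_tsv(paths.atc, ["ingredient_id", "atc_code", "atc_name"], atc_rows)
    write_ndfrt_records(records_a, paths.ndfrt)
    write_drugbank_xml(records_b, paths.drugbank)
    with open(paths.reference_groups, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ref_groups, fh, sort_keys=False)
    with open(paths.prescriptions, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "drug_id", "count"])
        for pid in patient_ids:
            for did in sorted(patients[pid]):
                writer.writerow([pid, did, 1])
    paths.ledger_path.write_text(ledger.to_json(), encoding="utf-8")
    return paths
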