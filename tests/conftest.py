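"""Shared fixtures: a small hand-built terminology covering salts,
combination products, topical products, obsolete concepts and partial ATC
coverage, loaded through the public TSV loader."""

from __future__ import annotations

import pytest

from ddicompare.terminology import load_terminology

CONCEPT_ROWS = [
    # ingredients
    ("I_DOXA", "doxacurium", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_CLOP", "clopidogrel", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_DILT", "diltiazem", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_LOVA", "lovastatin", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_OMEP", "omeprazole", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_PRIM", "Primidone", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_CARB", "Carbidopa", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_LEVO", "Levodopa", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_ZUCL", "zuclopenthixol", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_AVAN", "avanafil", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_HYDR", "hydrocortisone", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_AMOX", "amoxicillin", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_ETHI", "Ethinyl Estradiol", "INGREDIENT", "NOT_APPLICABLE", "0"),
    ("I_HEPT", "heptabarbital", "INGREDIENT", "NOT_APPLICABLE", "1"),  # obsolete
    # precise ingredients (salt/ester forms)
    ("P_DOXA", "doxacurium chloride", "PRECISE_INGREDIENT", "NOT_APPLICABLE", "0"),
    ("P_CLOP", "clopidogrel bisulfate", "PRECISE_INGREDIENT", "NOT_APPLICABLE", "0"),
    ("P_DILT", "diltiazem hydrochloride", "PRECISE_INGREDIENT", "NOT_APPLICABLE", "0"),
    ("P_ZUCA", "zuclopenthixol acetate", "PRECISE_INGREDIENT", "NOT_APPLICABLE", "0"),
    ("P_ZUCD", "zuclopenthixol deconoate", "PRECISE_INGREDIENT", "NOT_APPLICABLE", "0"),
    # clinical drugs
    ("D_PRIM", "Primidone 250 MG Oral Tablet", "CLINICAL_DRUG", "SYSTEMIC", "0"),
    ("D_CALE", "Carbidopa 25 MG/Levodopa 100 MG Oral Tablet", "CLINICAL_DRUG", "SYSTEMIC", "0"),
    ("D_DILT", "24 HR Diltiazem Hydrocloride 360 MG Extended Release Oral Capsule", "CLINICAL_DRUG", "SYSTEMIC", "0"),
    ("D_LOVA", "Lovastatin 20 MG Oral Tablet", "CLINICAL_DRUG", "SYSTEMIC", "0"),
    ("D_HYDR", "hydrocortisone 1% Topical Cream", "CLINICAL_DRUG", "TOPICAL", "0"),
    ("D_AMOX", "Amoxicillin 500 MG Oral Capsule", "CLINICAL_DRUG", "SYSTEMIC", "0"),
    ("D_ETHI", "Ethinyl Estradiol 0.02 MG Oral Tablet", "CLINICAL_DRUG", "SYSTEMIC", "0"),
]

RELATION_ROWS = [
    ("has_ingredient_base", "P_DOXA", "I_DOXA"),
    ("has_ingredient_base", "P_CLOP", "I_CLOP"),
    ("has_ingredient_base", "P_DILT", "I_DILT"),
    ("has_ingredient_base", "P_ZUCA", "I_ZUCL"),
    ("has_ingredient_base", "P_ZUCD", "I_ZUCL"),
    ("has_ingredient", "D_PRIM", "I_PRIM"),
    ("has_ingredient", "D_CALE", "I_CARB"),
    ("has_ingredient", "D_CALE", "I_LEVO"),
    ("has_ingredient", "D_DILT", "I_DILT"),
    ("has_ingredient", "D_LOVA", "I_LOVA"),
    ("has_ingredient", "D_HYDR", "I_HYDR"),
    ("has_ingredient", "D_AMOX", "I_AMOX"),
    ("has_ingredient", "D_ETHI", "I_ETHI"),
]

ATC_ROWS = [
    ("I_CLOP", "B01AC", "Platelet aggregation inhibitors excl. heparin"),
    ("I_DILT", "C08DB", "Benzothiazepine derivatives"),
    ("I_DILT", "C05AE", "Muscle relaxants"),  # second class for fan-out tests
    ("I_LOVA", "C10AA", "HMG CoA reductase inhibitors"),
    ("I_OMEP", "A02BC", "Proton pump inhibitors"),
    ("I_PRIM", "N03AA", "Barbiturates and derivatives"),
    ("I_CARB", "N04BA", "Dopa and dopa derivatives"),
    ("I_LEVO", "N04BA", "Dopa and dopa derivatives"),
    ("I_ZUCL", "N05AF", "Thioxanthene derivatives"),
    # avanafil deliberately has no ATC assignment
]


def _write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@pytest.fixture(scope="session")
def term_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("terminology")
    _write_tsv(
        d / "concepts.tsv",
        ["concept_id", "name", "term_type", "route_class", "obsolete"],
        CONCEPT_ROWS,
    )
    _write_tsv(
        d / "relations.tsv", ["rel_type", "source_id", "target_id"], RELATION_ROWS
    )
    _write_tsv(d / "atc.tsv", ["ingredient_id", "atc_code", "atc_name"], ATC_ROWS)
    return d


@pytest.fixture(scope="session")
def term(term_dir):
    return load_terminology(
        term_dir / "concepts.tsv", term_dir / "relations.tsv", term_dir / "atc.tsv"
    )
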