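"""Rendering of comparison results as JSON and aligned text tables."""

from __future__ import annotations

import dataclasses
import json

from .class_abstraction import ClassPairStats, ClassProfile
from .comparison import OverlapReport, ReferenceCoverage
from .screening import ScreeningResult
from .terminology import Terminology


def _table(header: list[str], rows: list[list[str]]) -> str:
    widths = [
        max(len(header[i]), *(len(r[i]) for r in rows)) if rows else len(header[i])
        for i in range(len(header))
    ]
    def fmt(cells):
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()
    lines = [fmt(header), fmt(["-" * w for w in widths])]
    lines.extend(fmt(r) for r in rows)
    return "\n".join(lines) + "\n"


def overlap_json(report: OverlapReport) -> str:
    return json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True)


def overlap_text(report: OverlapReport, label_a: str, label_b: str) -> str:
    rows = [
        [label_a, str(report.size_a), str(report.only_a),
         str(report.shared), f"{report.coverage_a_by_b_pct}%"],
        [label_b, str(report.size_b), str(report.only_b),
         str(report.shared), f"{report.coverage_b_by_a_pct}%"],
    ]
    return _table(
        ["source", "DDIs", "unique", "shared", "covered by other"], rows
    )


def reference_coverage_text(cov: ReferenceCoverage, source_label: str) -> str:
    rows = [
        [str(g.group_id), g.label, str(g.n_pairs),
         f"{g.matched} ({g.matched_pct}%)"]
        for g in cov.groups
    ]
    rows.append(
        ["", "TOTAL", str(cov.total_pairs),
         f"{cov.total_matched} ({cov.total_pct}%)"]
    )
    return _table(["grp", "group", "pairs", f"{source_label} matches"], rows)


def reference_coverage_json(cov: ReferenceCoverage) -> str:
    return json.dumps(dataclasses.asdict(cov), indent=2, sort_keys=True)


def class_pair_tsv(rows: list[ClassPairStats]) -> str:
    out = ["class_pair\ttotal\tonly_a\tonly_b\tshared\tjaccard"]
    for r in rows:
        out.append(
            f"{r.class_a} - {r.class_b}\t{r.total}\t{r.only_a}\t{r.only_b}"
            f"\t{r.shared}\t{r.jaccard:.2f}"
        )
    return "\n".join(out) + "\n"


def class_profile_tsv(
    a: list[ClassProfile], b: list[ClassProfile]
) -> str:
    by_code_a = {p.atc_code: p for p in a}
    by_code_b = {p.atc_code: p for p in b}
    out = ["class\tname\tddi_count_a\tdrug_count_a\tddi_count_b\tdrug_count_b"]
    for code in sorted(set(by_code_a) | set(by_code_b)):
        pa, pb = by_code_a.get(code), by_code_b.get(code)
        name = (pa or pb).atc_name
        out.append(
            f"{code}\t{name}\t{pa.ddi_count if pa else 0}\t"
            f"{pa.drug_count if pa else 0}\t{pb.ddi_count if pb else 0}\t"
            f"{pb.drug_count if pb else 0}"
        )
    return "\n".join(out) + "\n"


def screening_json(result: ScreeningResult) -> str:
    payload = {
        "total_pairs": result.total_pairs,
        "unique_pairs": result.unique_pairs,
        "per_source_matches": {
            name: {"total": s.total, "unique": s.unique}
            for name, s in sorted(result.per_source_matches.items())
        },
        "both_sources": {
            "total": result.both_sources.total,
            "unique": result.both_sources.unique,
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def top_pairs_tsv(
    rows: list[tuple], term: Terminology | None = None
) -> str:
    out = ["pair\tfrequency\tmatched_by"]
    for pair, freq, sources in rows:
        if term is not None:
            label = (
                f"{term.concepts[pair.low_id].name}-"
                f"{term.concepts[pair.high_id].name}"
            )
        else:
            label = f"{pair.low_id}-{pair.high_id}"
        out.append(f"{label}\t{freq}\t{','.join(sorted(sources))}")
    return "\n".join(out) + "\n"
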