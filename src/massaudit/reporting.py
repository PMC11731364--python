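"""Per-measurement lines, per-file verdicts, corpus summaries and writers.

Output formatting is deliberately rigid — masses at 4 decimal places, ppm at
2, fixed column order — so that re-running the tool on identical inputs
yields byte-identical reports, and the CSV and JSON forms of a report carry
exactly the same information.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .diagnostics import Diagnosis, DiagnosisCategory, DiagnosticConfig, classify
from .extraction import (
    AMMRecord,
    extract_page_text,
    find_amm_records,
    list_documents,
    SourceLocation,
)

__all__ = [
    "RecordReport",
    "FileReport",
    "CorpusSummary",
    "CSV_COLUMNS",
    "render_measurement_line",
    "scan_folder",
    "summarize",
    "write_records_csv",
    "write_records_json",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "file",
    "page",
    "formula",
    "ion",
    "calcd",
    "recalc",
    "found",
    "ppm_calcd",
    "ppm_recalc",
    "category",
    "suggestion",
    "explanation",
]

#: Marker appended to deviations beyond the configured threshold.
FLAG_TOKEN = "***"

#: Table-style summary labels for specific formula edits.
_EDIT_LABELS = {
    "+H": "one_H_atom_added",
    "+Na": "one_Na_atom_added",
    "+O": "one_O_atom_added",
    "+C": "one_C_atom_added",
    "+2H": "two_H_atoms_added",
    "+2O": "two_O_atoms_added",
    "-H": "one_H_atom_removed",
    "-Na": "one_Na_atom_removed",
    "-CH2": "one_CH2_group_removed",
}


@dataclass(frozen=True)
class RecordReport:
    """One record paired with its diagnosis, ready for serialization."""

    record: AMMRecord
    diagnosis: Diagnosis

    def row(self) -> dict[str, str]:
        d = self.diagnosis
        return {
            "file": self.record.location.file_path,
            "page": str(self.record.location.page),
            "formula": self.record.formula_text,
            "ion": self.record.ion_text,
            "calcd": self.record.calcd_text,
            "recalc": "" if d.recalculated_mass is None else f"{d.recalculated_mass:.4f}",
            "found": self.record.found_text,
            "ppm_calcd": "" if d.ppm_calcd_vs_found is None else f"{d.ppm_calcd_vs_found:.2f}",
            "ppm_recalc": "" if d.ppm_recalc_vs_found is None else f"{d.ppm_recalc_vs_found:.2f}",
            "category": d.category.value,
            "suggestion": d.suggestion or "",
            "explanation": d.explanation,
        }


@dataclass(frozen=True)
class FileReport:
    """Per-file verdict: category tallies and whether the file is clean."""

    file: str
    n_records: int
    n_by_category: dict[str, int]
    n_by_edit: dict[str, int]
    clean: bool


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level tallies in the style of a screening summary table."""

    n_files: int
    n_files_with_amm: int
    n_clean_files: int
    n_records: int
    n_amm_errors: int
    n_amm_errors_without_electron: int
    n_by_category: dict[str, int]
    n_by_edit: dict[str, int]
    pct_files_with_amm: int
    pct_clean_files: int

    def as_dict(self) -> dict:
        d = {
            "files": self.n_files,
            "files_with_amm_data": self.n_files_with_amm,
            "files_without_amm_errors": self.n_clean_files,
            "amms": self.n_records,
            "amm_errors": self.n_amm_errors,
            "amm_errors_without_electron": self.n_amm_errors_without_electron,
            "pct_files_with_amm_data": self.pct_files_with_amm,
            "pct_files_without_amm_errors": self.pct_clean_files,
            "molecular_weight_errors": self.n_by_category.get(
                DiagnosisCategory.MOLECULAR_WEIGHT.value, 0
            ),
            "nominal_mass_errors": self.n_by_category.get(
                DiagnosisCategory.NOMINAL_MASS_ADDUCT.value, 0
            ),
            "electron_mass_errors": self.n_by_category.get(
                DiagnosisCategory.ELECTRON_MASS.value, 0
            ),
            "transposed_digits": self.n_by_category.get(
                DiagnosisCategory.TRANSPOSED_DIGITS.value, 0
            ),
            "typographical_errors": self.n_by_category.get(
                DiagnosisCategory.SUBSTITUTED_DIGIT.value, 0
            ),
        }
        for label in _EDIT_LABELS.values():
            d[label] = self.n_by_edit.get(label, 0)
        other = sum(
            n for e, n in self.n_by_edit.items() if e not in _EDIT_LABELS.values()
        )
        d["other_formula_edits"] = other
        d["by_category"] = dict(sorted(self.n_by_category.items()))
        return d


def render_measurement_line(
    report: RecordReport, config: DiagnosticConfig | None = None
) -> str:
    """One-line analysis of a measurement.

    The printed calculated mass is followed by the recalculated value in
    parentheses, then the found mass and the ppm deviations of the found mass
    against the calculated and recalculated (parenthesised) values; any
    deviation beyond the threshold is flagged.
    """
    config = config or DiagnosticConfig()
    rec, d = report.record, report.diagnosis
    recalc = "?" if d.recalculated_mass is None else f"{d.recalculated_mass:.4f}"
    calcd = rec.calcd_text or "?"
    found = rec.found_text or "?"

    def _ppm(p: Optional[float]) -> str:
        if p is None:
            return "?"
        flag = f" {FLAG_TOKEN}" if abs(p) > config.ppm_threshold else ""
        return f"{p:+.2f} ppm{flag}"

    pieces = [
        f"{rec.location.file_path}:{rec.location.page}",
        rec.formula_text or "?",
        rec.ion_text or "?",
        f"{calcd} ({recalc})",
        found,
        f"{_ppm(d.ppm_calcd_vs_found)} ({_ppm(d.ppm_recalc_vs_found)})",
        f"{d.category.value}: {d.explanation}" if d.explanation else d.category.value,
    ]
    return " | ".join(pieces)


def file_report(file: str, reports: Sequence[RecordReport]) -> FileReport:
    by_cat: dict[str, int] = {}
    by_edit: dict[str, int] = {}
    for r in reports:
        cat = r.diagnosis.category.value
        by_cat[cat] = by_cat.get(cat, 0) + 1
        if r.diagnosis.edit:
            label = _EDIT_LABELS.get(
                r.diagnosis.edit, f"edit_{r.diagnosis.edit}"
            )
            by_edit[label] = by_edit.get(label, 0) + 1
    clean = all(
        r.diagnosis.category is DiagnosisCategory.CONSISTENT for r in reports
    )
    return FileReport(
        file=file,
        n_records=len(reports),
        n_by_category=by_cat,
        n_by_edit=by_edit,
        clean=clean and bool(reports),
    )


def summarize(file_reports: Iterable[FileReport]) -> CorpusSummary:
    """Aggregate per-file verdicts into a corpus summary.

    Totals are sums over files (hence invariant to file order); percentages
    are rounded to integer percent.  Threshold-only exceedances are tallied
    in their own category and counted among AMM errors; the
    "without electron" error count additionally excludes the electron-mass
    class, mirroring the convention of splitting out that dominant minor
    error.
    """
    reports = list(file_reports)
    n_files = len(reports)
    n_with = sum(1 for r in reports if r.n_records > 0)
    n_clean = sum(1 for r in reports if r.n_records > 0 and r.clean)
    n_records = sum(r.n_records for r in reports)
    by_cat: dict[str, int] = {}
    by_edit: dict[str, int] = {}
    for r in reports:
        for c, n in r.n_by_category.items():
            by_cat[c] = by_cat.get(c, 0) + n
        for e, n in r.n_by_edit.items():
            by_edit[e] = by_edit.get(e, 0) + n
    consistent = by_cat.get(DiagnosisCategory.CONSISTENT.value, 0)
    electron = by_cat.get(DiagnosisCategory.ELECTRON_MASS.value, 0)
    n_errors = n_records - consistent
    return CorpusSummary(
        n_files=n_files,
        n_files_with_amm=n_with,
        n_clean_files=n_clean,
        n_records=n_records,
        n_amm_errors=n_errors,
        n_amm_errors_without_electron=n_errors - electron,
        n_by_category=by_cat,
        n_by_edit=by_edit,
        pct_files_with_amm=round(100 * n_with / n_files) if n_files else 0,
        pct_clean_files=round(100 * n_clean / n_with) if n_with else 0,
    )


def scan_folder(
    folder: str | Path,
    config: DiagnosticConfig | None = None,
    extensions: Sequence[str] = (".pdf", ".txt"),
) -> tuple[list[RecordReport], list[FileReport]]:
    """Run the full audit over every document under ``folder``.

    Documents are visited in sorted order; unreadable files are skipped with
    a logged warning.  Returns per-record reports and per-file verdicts.
    """
    config = config or DiagnosticConfig()
    all_reports: list[RecordReport] = []
    per_file: list[FileReport] = []
    for doc in list_documents(folder, extensions=extensions):
        reports: list[RecordReport] = []
        for page_no, page in enumerate(extract_page_text(doc), start=1):
            stub = SourceLocation(file_path=str(doc), page=page_no)
            for record in find_amm_records(page, stub):
                reports.append(RecordReport(record, classify(record, config)))
        per_file.append(file_report(str(doc), reports))
        all_reports.extend(reports)
    return all_reports, per_file


def write_records_csv(reports: Sequence[RecordReport], path: str | Path) -> None:
    """Write one CSV row per record, fixed column order and formatting."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for r in reports:
            writer.writerow(r.row())


def write_records_json(reports: Sequence[RecordReport], path: str | Path) -> None:
    """Write the same report content as JSON, key-for-column with the CSV."""
    rows = [r.row() for r in reports]
    Path(path).write_text(
        json.dumps(rows, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
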