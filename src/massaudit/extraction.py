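"""Locate documents and extract accurate-mass quadruplets from page text.

Each HRMS statement in an experimental section carries a *quadruplet*:
molecular formula, measured ion label (e.g. ``[M + Na]+``), the reported
calculated mass and the reported found mass.  This module finds those
statements with a table-driven grammar that tolerates the common dialect
variants ("HRMS"/"HR-MS", "Calcd"/"calcd."/"calc'd"/"Calculated", ion label
before or after the formula) and returns records carrying their exact source
location, so every claim in a report can be traced back to the page.

PDF text extraction is a pluggable thin layer: plain ``.txt`` documents (one
page per form-feed) are always supported; ``.pdf`` documents are read through
``pypdf`` when it is importable and skipped with a logged warning otherwise.
Unreadable or encrypted files are skipped, never fatal — robustness over a
large corpus is the point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .masses import FormulaError, IonSpecies, normalize_typography, parse_formula

__all__ = [
    "SourceLocation",
    "AMMRecord",
    "list_documents",
    "normalize_page_text",
    "extract_page_text",
    "find_amm_records",
    "normalize_ion_label",
]

logger = logging.getLogger(__name__)

MALFORMED_FLAG = "MALFORMED"


@dataclass(frozen=True)
class SourceLocation:
    """Where a record came from: file, 1-based page, span into the page text."""

    file_path: str
    page: int = 1
    char_span: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class AMMRecord:
    """One extracted accurate-mass quadruplet, verbatim, with provenance."""

    raw_text: str
    formula_text: str
    ion_text: str
    calcd_text: str
    found_text: str
    location: SourceLocation
    flags: tuple[str, ...] = field(default_factory=tuple)


def list_documents(folder: str | Path, extensions: Sequence[str] = (".pdf",)) -> list[Path]:
    """Recursively list documents under ``folder`` in deterministic sorted order."""
    root = Path(folder)
    if not root.is_dir():
        raise FileNotFoundError(f"not a folder: {folder}")
    wanted = {e.lower() for e in extensions}
    return sorted(
        p for p in root.rglob("*") if p.is_file() and p.suffix.lower() in wanted
    )


_HYPHEN_BREAK = re.compile(r"-\n(?=\w)")
_LINE_BREAK = re.compile(r"\s*\n\s*")
_MULTISPACE = re.compile(r"[ \t]+")


def normalize_page_text(raw: str) -> str:
    """Collapse a page to one normalized line of text.

    End-of-line hyphenation is joined, intra-paragraph line breaks become
    single spaces, runs of whitespace collapse, and Unicode typography
    (minus signs, thin spaces, sub/superscripts) is mapped to ASCII.
    """
    t = normalize_typography(raw)
    t = _HYPHEN_BREAK.sub("", t)
    t = _LINE_BREAK.sub(" ", t)
    t = _MULTISPACE.sub(" ", t)
    return t.strip()


def extract_page_text(doc: str | Path) -> list[str]:
    """Return one normalized text string per page of ``doc``.

    ``.txt`` documents use form-feed (``\\f``) as the page separator.  PDF
    support requires ``pypdf``; when it is missing, or a file is unreadable
    or encrypted, the document is skipped with a warning and an empty list
    is returned.
    """
    path = Path(doc)
    suffix = path.suffix.lower()
    if suffix == ".txt":
        try:
            raw = path.read_text(encoding="utf-8", errors="replace")
        except OSError as exc:
            logger.warning("skipping unreadable document %s: %s", path, exc)
            return []
        return [normalize_page_text(page) for page in raw.split("\f")]
    if suffix == ".pdf":
        try:
            import pypdf  # optional backend
        except ImportError:
            logger.warning("skipping %s: no PDF backend (pypdf) available", path)
            return []
        try:
            reader = pypdf.PdfReader(str(path))
            if reader.is_encrypted:
                logger.warning("skipping encrypted document %s", path)
                return []
            return [normalize_page_text(p.extract_text() or "") for p in reader.pages]
        except Exception as exc:  # any producer quirk: skip, never crash
            logger.warning("skipping unreadable document %s: %s", path, exc)
            return []
    logger.warning("skipping %s: unsupported document type", path)
    return []


# ---------------------------------------------------------------------------
# The HRMS statement grammar (table-driven: dialects are data, not code)
# ---------------------------------------------------------------------------

#: Tokens that anchor an HRMS statement.
ANCHOR_TOKENS = ["HRMS", "HR-MS", "HRESIMS", "HR-ESIMS", "HRESI-MS", "HR-ESI-MS"]

#: "Calculated" spellings (matched case-insensitively; optional trailing dot).
CALCD_TOKENS = ["calculated", "calc'd", "calcd", "calc"]

#: "Found" spellings.
FOUND_TOKENS = ["found", "observed", "obsd"]

#: Both the calcd and found numbers must start within this many characters of
#: the anchor, to avoid capturing numbers from a neighbouring sentence.
MAX_ANCHOR_DISTANCE = 120

_ANCHOR_RX = re.compile("|".join(re.escape(t) for t in ANCHOR_TOKENS), re.IGNORECASE)

_ION = r"\[\s*\d?\s*M(?:\s*[+-]\s*\d{0,2}[A-Za-z][A-Za-z0-9]{0,5})*\s*\]\s*\d?\s*[+-]|M\s?[+-](?![A-Za-z0-9.])"
_FORMULA = r"(?-i:[A-Z][a-z]?\d*(?:[A-Z][a-z]?\d*)*)"
_NUMBER = r"\d{2,5}\.\d{3,5}"
_CALCD = "(?:" + "|".join(re.escape(t) for t in CALCD_TOKENS) + r")\.?"
_FOUND = "(?:" + "|".join(re.escape(t) for t in FOUND_TOKENS) + r")\.?"
_GAP = r"[\s:;,]{0,4}"

# Dialect patterns are tried in order at each anchor; first match wins.  The
# formula sub-pattern is case-sensitive even though the keywords are not.
DIALECT_PATTERNS: list[re.Pattern[str]] = [
    re.compile(p, re.IGNORECASE)
    for p in [
        # ion label before "Calcd for": HRMS (ESI/Q-TOF) m/z: [M + Na]+ Calcd
        # for C13H17NO3Na 258.1101; Found 258.1074
        rf"(?P<anchor>{_ANCHOR_RX.pattern})(?:\s*\([^()]{{0,40}}\))?{_GAP}"
        rf"(?:m/z){_GAP}(?P<ion>{_ION}){_GAP}"
        rf"{_CALCD}\s*(?:for\s*)?(?P<formula>{_FORMULA})[\s:=,]*(?P<calcd>{_NUMBER})"
        rf"(?:{_GAP}(?:{_FOUND})[\s:=,]*(?P<found>{_NUMBER}))?",
        # same, "m/z" omitted
        rf"(?P<anchor>{_ANCHOR_RX.pattern})(?:\s*\([^()]{{0,40}}\))?{_GAP}"
        rf"(?P<ion>{_ION}){_GAP}"
        rf"{_CALCD}\s*(?:for\s*)?(?P<formula>{_FORMULA})[\s:=,]*(?P<calcd>{_NUMBER})"
        rf"(?:{_GAP}(?:{_FOUND})[\s:=,]*(?P<found>{_NUMBER}))?",
        # ion label after the formula: HRMS m/z calcd for C10H14NO [M + H]+
        # 180.1019, found 180.1022
        rf"(?P<anchor>{_ANCHOR_RX.pattern})(?:\s*\([^()]{{0,40}}\))?{_GAP}"
        rf"(?:m/z)?{_GAP}"
        rf"{_CALCD}\s*(?:for\s*)?(?P<formula>{_FORMULA})\s*(?P<ion>{_ION})[\s:=,]*(?P<calcd>{_NUMBER})"
        rf"(?:{_GAP}(?:{_FOUND})[\s:=,]*(?P<found>{_NUMBER}))?",
        # calcd value after ion but formula first, found-only dialects:
        # HRMS (ESI) m/z [M + H]+ 180.1019 found 180.1022 (no "Calcd for")
        rf"(?P<anchor>{_ANCHOR_RX.pattern})(?:\s*\([^()]{{0,40}}\))?{_GAP}"
        rf"(?:m/z)?{_GAP}(?P<ion>{_ION})[\s:=,]*(?P<calcd>{_NUMBER})"
        rf"{_GAP}(?:{_FOUND})[\s:=,]*(?P<found>{_NUMBER})",
    ]
]


def find_amm_records(page_text: str, location_stub: SourceLocation) -> list[AMMRecord]:
    """Scan normalized page text for HRMS statements.

    Every grammar match yields one :class:`AMMRecord` whose ``raw_text`` is a
    verbatim substring of ``page_text`` at its ``char_span``.  A statement
    missing its calcd or found number is kept with the field empty and a
    ``MALFORMED`` flag rather than dropped.  Matches never overlap.
    """
    records: list[AMMRecord] = []
    pos = 0
    while True:
        anchor = _ANCHOR_RX.search(page_text, pos)
        if anchor is None:
            break
        match = None
        for pattern in DIALECT_PATTERNS:
            m = pattern.match(page_text, anchor.start())
            if m:
                match = m
                break
        if match is None:
            pos = anchor.end()
            continue
        groups = match.groupdict()
        calcd = groups.get("calcd") or ""
        found = groups.get("found") or ""
        start = match.start()
        # distance guard against cross-sentence capture
        if calcd and match.start("calcd") - start > MAX_ANCHOR_DISTANCE:
            calcd = ""
        if found and match.start("found") - start > MAX_ANCHOR_DISTANCE:
            found = ""
        flags: tuple[str, ...] = ()
        if not calcd or not found:
            flags = (MALFORMED_FLAG,)
        end = match.end("found") if found else match.end("calcd") if calcd else match.end()
        records.append(
            AMMRecord(
                raw_text=page_text[start:end],
                formula_text=groups.get("formula") or "",
                ion_text=groups.get("ion") or "",
                calcd_text=calcd,
                found_text=found,
                location=SourceLocation(
                    file_path=location_stub.file_path,
                    page=location_stub.page,
                    char_span=(start, end),
                ),
                flags=flags,
            )
        )
        pos = end
    return records


_ION_LABEL_RX = re.compile(
    r"^\[\s*(?P<mult>\d?)\s*M(?P<terms>(?:\s*[+-]\s*\d{0,2}[A-Za-z][A-Za-z0-9]{0,5})*)\s*\]"
    r"\s*(?P<zmag>\d?)\s*(?P<zsign>[+-])$"
)
_BARE_ION_RX = re.compile(r"^M\s?(?P<zsign>[+-])$")
_TERM_RX = re.compile(r"([+-])\s*(\d{0,2})([A-Za-z][A-Za-z0-9]{0,5})")


def normalize_ion_label(ion_text: str) -> IonSpecies:
    """Interpret an ion label such as ``"[2M + Na]+"`` as an :class:`IonSpecies`.

    Whitespace- and Unicode-sign-insensitive.  Raises :class:`FormulaError`
    for labels outside the grammar; callers keep the record and flag it
    unparseable rather than dropping it.
    """
    s = normalize_typography(ion_text).strip()
    m = _BARE_ION_RX.match(s)
    if m:  # radical ion M+ / M-
        return IonSpecies(charge=1 if m.group("zsign") == "+" else -1)
    m = _ION_LABEL_RX.match(s)
    if m is None:
        raise FormulaError(f"unrecognized ion label {ion_text!r}")
    multiplier = int(m.group("mult") or 1)
    added: dict[str, int] = {}
    removed: dict[str, int] = {}
    for sign, count, group in _TERM_RX.findall(m.group("terms")):
        try:
            part = parse_formula(group)
        except FormulaError as exc:
            raise FormulaError(
                f"unrecognized adduct {group!r} in ion label {ion_text!r}"
            ) from exc
        k = int(count or 1)
        target = added if sign == "+" else removed
        for el, n in part.counts.items():
            target[el] = target.get(el, 0) + n * k
    zmag = int(m.group("zmag") or 1)
    charge = zmag if m.group("zsign") == "+" else -zmag
    return IonSpecies(multiplier=multiplier, added=added, removed=removed, charge=charge)


def iter_document_records(doc: str | Path) -> Iterable[AMMRecord]:
    """Extract every AMM record from one document, page by page."""
    for page_no, page in enumerate(extract_page_text(doc), start=1):
        stub = SourceLocation(file_path=str(doc), page=page_no)
        yield from find_amm_records(page, stub)
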