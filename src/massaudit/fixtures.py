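"""Seeded generator of synthetic Supporting-Information text with labeled errors.

Real SI corpora cannot be redistributed, so the test bed is generated: each
record starts from a true drug-like formula and ion, the true calculated and
found masses are computed from first principles (found jittered within
±5 ppm, below the default 10 ppm threshold, so the injected error class and
not measurement noise determines the diagnosis), and then exactly one
corruption from the error taxonomy is applied — drop the adduct atoms from
the formula, add the nominal instead of the isotopic adduct mass, use the
average mass, skip the electron correction, transpose or substitute a digit,
perturb the formula by a vocabulary edit, or omit the Found clause.

Constructions are kept unambiguous: a corruption whose corrupted value
accidentally lands within the match tolerance of a *different* hypothesis for
that record (e.g. a digit substitution of +0.01 Da mimicking a nominal-mass
Na addition) is rejected and redrawn, as is a category that is not injectable
for the drawn formula (e.g. removing Na from a sodium-free formula).

Every emitted record appears exactly once in the ground-truth ledger.  The
same seed always yields an identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .diagnostics import DiagnosisCategory, DiagnosticConfig, search_digit_typos
from .masses import (
    ELECTRON_MASS,
    Formula,
    FormulaError,
    IonSpecies,
    average_mass,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
)

__all__ = [
    "DEFAULT_FORMULA_POOL",
    "DEFAULT_INJECTION",
    "ErrorInjectionSpec",
    "LedgerEntry",
    "CorpusFixture",
    "generate_corpus",
    "write_corpus",
]

#: 50 drug-like CHNOS(F,Cl) molecular formulas, monoisotopic 150-800 Da.
DEFAULT_FORMULA_POOL: tuple[str, ...] = (
    "C8H9NO2",        # paracetamol
    "C9H8O4",         # aspirin
    "C8H17NO2",       # pregabalin
    "C9H17NO2",       # gabapentin
    "C6H9N3O3",       # metronidazole
    "C10H12N2O",      # serotonin
    "C8H10N4O2",      # caffeine
    "C9H11NO4",       # levodopa
    "C13H18O2",       # ibuprofen
    "C10H11N3O3S",    # sulfamethoxazole
    "C13H16N2O2",     # melatonin
    "C14H14O3",       # naproxen
    "C14H22N2O",      # lidocaine
    "C13H16ClNO",     # ketamine
    "C13H18ClNO",     # bupropion
    "C16H25NO2",      # tramadol
    "C15H25NO3",      # metoprolol
    "C14H22N2O3",     # atenolol
    "C16H21NO2",      # propranolol
    "C17H27NO2",      # venlafaxine
    "C14H18N4O3",     # trimethoprim
    "C17H19NO3",      # morphine
    "C18H21NO3",      # codeine
    "C16H13ClN2O",    # diazepam
    "C14H11Cl2NO2",   # diclofenac
    "C18H19NOS",      # duloxetine
    "C19H28O2",       # testosterone
    "C18H24O2",       # estradiol
    "C17H18F3NO",     # fluoxetine
    "C17H17Cl2N",     # sertraline
    "C19H16O4",       # warfarin
    "C17H13ClN4",     # alprazolam
    "C17H20N4S",      # olanzapine
    "C20H24N2O2",     # quinine
    "C18H19ClN4",     # clozapine
    "C16H18N2O4S",    # penicillin G
    "C17H18FN3O3",    # ciprofloxacin
    "C17H19N3O3S",    # omeprazole
    "C21H26O5",       # prednisone
    "C16H19N3O5S",    # amoxicillin
    "C22H23N3O4",     # erlotinib
    "C21H23ClFNO2",   # haloperidol
    "C22H29FO5",      # dexamethasone
    "C21H25N3O2S",    # quetiapine
    "C20H25ClN2O5",   # amlodipine
    "C23H27FN4O2",    # risperidone
    "C25H38O5",       # simvastatin
    "C22H30N6O4S",    # sildenafil
    "C29H31N7O",      # imatinib
    "C33H35FN2O5",    # atorvastatin
)

_ION_CHOICES: tuple[tuple[IonSpecies, float], ...] = (
    (IonSpecies(added={"H": 1}, charge=1), 0.50),
    (IonSpecies(added={"Na": 1}, charge=1), 0.35),
    (IonSpecies(removed={"H": 1}, charge=-1), 0.15),
)

_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("acs", "HRMS (ESI/Q-TOF) m/z: {ion} Calcd for {formula} {calcd}; Found {found}."),
    ("jorg", "HRMS (ESI) m/z calcd for {formula} {ion} {calcd}, found {found}."),
    ("dotted", "HR-MS (ESI-TOF): {ion} Calcd. for {formula} {calcd}; found {found}."),
    ("apos", "HRMS (ESI) m/z: {ion} calc'd for {formula} {calcd}; Found {found}."),
)
_MALFORMED_TEMPLATE = ("nofound", "HRMS (ESI/Q-TOF) m/z: {ion} Calcd for {formula} {calcd}.")

_FILLER = (
    "Compound {n} was obtained as a colorless solid (yield {y}%). ",
    "The title compound {n} was isolated after column chromatography ({y}% yield). ",
    "Compound {n}: pale yellow oil, {y}% yield. ",
)


@dataclass(frozen=True)
class ErrorInjectionSpec:
    """Rate of one injected error category; remaining records are CONSISTENT."""

    category: DiagnosisCategory
    rate: float


#: Default injection mix: 40% of records are left fully consistent, echoing
#: the roughly 40% of real SI files that pass the audit untouched.
DEFAULT_INJECTION: tuple[ErrorInjectionSpec, ...] = (
    ErrorInjectionSpec(DiagnosisCategory.ELECTRON_MASS, 0.12),
    ErrorInjectionSpec(DiagnosisCategory.ADDUCT_OMITTED, 0.08),
    ErrorInjectionSpec(DiagnosisCategory.THRESHOLD_EXCEEDED, 0.07),
    ErrorInjectionSpec(DiagnosisCategory.NOMINAL_MASS_ADDUCT, 0.06),
    ErrorInjectionSpec(DiagnosisCategory.MOLECULAR_WEIGHT, 0.06),
    ErrorInjectionSpec(DiagnosisCategory.TRANSPOSED_DIGITS, 0.06),
    ErrorInjectionSpec(DiagnosisCategory.SUBSTITUTED_DIGIT, 0.06),
    ErrorInjectionSpec(DiagnosisCategory.FORMULA_EDIT, 0.05),
    ErrorInjectionSpec(DiagnosisCategory.MALFORMED, 0.04),
)


@dataclass(frozen=True)
class LedgerEntry:
    """Ground truth for one generated record."""

    record_id: int
    file: str
    page: int
    seq: int  # 0-based order of the record within its page
    category: DiagnosisCategory
    dialect: str
    printed_formula: str
    true_formula: str  # full ion formula (Hill)
    ion_label: str
    true_calcd: float
    printed_calcd: str
    printed_found: str
    edit: Optional[str] = None


@dataclass(frozen=True)
class CorpusFixture:
    """Generated documents (file name -> text, pages separated by ``\\f``)
    plus the complete ground-truth ledger."""

    documents: dict[str, str]
    ledger: tuple[LedgerEntry, ...]


def _ion_label_text(ion: IonSpecies, rng: random.Random) -> str:
    label = ion.label()
    if rng.random() < 0.5:
        label = label.replace(" ", "")
    return label


def _candidate_values(formula: Formula, ion: IonSpecies) -> list[tuple[float, float]]:
    """All (value, tolerance) pairs any pre-typo hypothesis could match for a
    record printing ``formula`` with ``ion`` — used to keep corruptions
    unambiguous.  Independent re-derivation of the candidate algebra."""
    cfg = DiagnosticConfig()
    tol, mw_tol = cfg.match_tolerance, cfg.mw_tolerance
    az = abs(ion.charge)
    out: list[tuple[float, float]] = []
    mono = monoisotopic_mass(formula)
    out.append(((mono - ion.charge * ELECTRON_MASS) / az, tol))
    out.append((mono / az, tol))
    out.append((average_mass(formula) / az, mw_tol))
    try:
        ion_counts = ion.ion_counts(formula)
    except FormulaError:
        ion_counts = None
    if ion_counts is not None and ion_counts.counts != formula.counts:
        m2 = monoisotopic_mass(ion_counts)
        out.append(((m2 - ion.charge * ELECTRON_MASS) / az, tol))
        out.append((m2 / az, tol))
        out.append((average_mass(ion_counts) / az, mw_tol))
    if ion.added:
        nom = float(nominal_mass(ion.added))
        rem = monoisotopic_mass(ion.removed) if ion.removed else 0.0
        bases = [mono * ion.multiplier - rem]
        if formula.contains(ion.added):
            bases.append(monoisotopic_mass(formula.subtract(ion.added)) - rem)
        for b in bases:
            out.append(((b + nom) / az, tol))
            out.append(((b + nom - ion.charge * ELECTRON_MASS) / az, tol))
    return out


def _collides(value: float, candidates: Sequence[tuple[float, float]]) -> bool:
    return any(abs(value - c) <= t * 1.5 for c, t in candidates)


_EDIT_CHOICES: tuple[tuple[str, dict[str, int]], ...] = tuple(
    (sign + name, dict(counts))
    for name, counts in [
        ("H", {"H": 1}),
        ("2H", {"H": 2}),
        ("Na", {"Na": 1}),
        ("O", {"O": 1}),
        ("2O", {"O": 2}),
        ("C", {"C": 1}),
        ("CH2", {"C": 1, "H": 2}),
        ("F", {"F": 1}),
        ("Cl", {"Cl": 1}),
    ]
    for sign in ("+", "-")
)


def generate_corpus(
    formula_pool: Sequence[str] = DEFAULT_FORMULA_POOL,
    specs: Sequence[ErrorInjectionSpec] = DEFAULT_INJECTION,
    n_records: int = 200,
    seed: int = 0,
    records_per_page: int = 5,
    pages_per_file: int = 4,
) -> CorpusFixture:
    """Generate a labeled synthetic SI corpus.

    ``specs`` gives the fraction of records per injected category (must sum
    to at most 1; the remainder is CONSISTENT).  Records are laid out
    ``records_per_page`` per page and ``pages_per_file`` pages per ``.txt``
    document.  Deterministic in ``seed``.
    """
    total_rate = sum(s.rate for s in specs)
    if total_rate > 1 + 1e-9:
        raise ValueError("injection rates sum to more than 1")
    rng = random.Random(seed)
    pool = [parse_formula(f) for f in formula_pool]
    if not pool:
        raise ValueError("formula pool is empty")

    # integer category tally: floors, then largest remainders
    raw = [(s.category, s.rate * n_records) for s in specs]
    counts = {c: int(x) for c, x in raw}
    remainder = n_records - sum(counts.values()) - int(
        round((1 - total_rate) * n_records)
    )
    for c, x in sorted(raw, key=lambda cx: cx[1] - int(cx[1]), reverse=True):
        if remainder <= 0:
            break
        counts[c] += 1
        remainder -= 1
    categories = [c for c, k in counts.items() for _ in range(k)]
    categories += [DiagnosisCategory.CONSISTENT] * (n_records - len(categories))
    rng.shuffle(categories)

    ion_specs = [i for i, _ in _ION_CHOICES]
    ion_weights = [w for _, w in _ION_CHOICES]

    entries: list[LedgerEntry] = []
    paragraphs: list[str] = []
    for record_id, category in enumerate(categories):
        for _ in range(200):  # resample until the construction is unambiguous
            formula = rng.choice(pool)
            ion = rng.choices(ion_specs, weights=ion_weights, k=1)[0]
            built = _build_record(record_id, category, formula, ion, rng)
            if built is not None:
                break
        else:
            raise RuntimeError(f"could not construct a {category.value} record")
        sentence, entry_stub = built
        filler = rng.choice(_FILLER).format(n=record_id + 1, y=rng.randint(40, 97))
        paragraphs.append(filler + sentence)
        entries.append(entry_stub)

    documents: dict[str, str] = {}
    final: list[LedgerEntry] = []
    per_file = records_per_page * pages_per_file
    for start in range(0, len(paragraphs), per_file):
        file_idx = start // per_file
        name = f"si_{file_idx + 1:04d}.txt"
        pages = []
        chunk = paragraphs[start : start + per_file]
        chunk_entries = entries[start : start + per_file]
        for p in range(0, len(chunk), records_per_page):
            page_no = p // records_per_page + 1
            pages.append("\n".join(chunk[p : p + records_per_page]))
            for seq, e in enumerate(chunk_entries[p : p + records_per_page]):
                final.append(
                    LedgerEntry(
                        record_id=e.record_id,
                        file=name,
                        page=page_no,
                        seq=seq,
                        category=e.category,
                        dialect=e.dialect,
                        printed_formula=e.printed_formula,
                        true_formula=e.true_formula,
                        ion_label=e.ion_label,
                        true_calcd=e.true_calcd,
                        printed_calcd=e.printed_calcd,
                        printed_found=e.printed_found,
                        edit=e.edit,
                    )
                )
        documents[name] = "\f".join(pages)
    return CorpusFixture(documents=documents, ledger=tuple(final))


def _build_record(
    record_id: int,
    category: DiagnosisCategory,
    formula: Formula,
    ion: IonSpecies,
    rng: random.Random,
) -> Optional[tuple[str, LedgerEntry]]:
    """Construct one record of the requested category, or ``None`` to resample."""
    az = abs(ion.charge)
    try:
        ion_formula = ion.ion_counts(formula)
    except FormulaError:
        return None
    true_ref = (monoisotopic_mass(ion_formula) - ion.charge * ELECTRON_MASS) / az
    calcd_text = f"{true_ref:.4f}"
    jitter = rng.uniform(-5, 5)
    found_text = f"{true_ref * (1 + jitter * 1e-6):.4f}"
    printed_formula = ion_formula.hill()  # ACS convention: formula names the ion
    neutral = formula.hill()
    dialect, template = _TEMPLATES[rng.randrange(len(_TEMPLATES))]
    edit_label: Optional[str] = None

    if category == DiagnosisCategory.CONSISTENT:
        pass
    elif category == DiagnosisCategory.THRESHOLD_EXCEEDED:
        off = rng.uniform(15, 40) * rng.choice((-1, 1))
        found_text = f"{true_ref * (1 + off * 1e-6):.4f}"
    elif category == DiagnosisCategory.ELECTRON_MASS:
        calcd_text = f"{monoisotopic_mass(ion_formula) / az:.4f}"
    elif category == DiagnosisCategory.ADDUCT_OMITTED:
        if not ion.added and not ion.removed:
            return None
        printed_formula = neutral
    elif category == DiagnosisCategory.NOMINAL_MASS_ADDUCT:
        if not ion.added:
            return None
        printed_formula = neutral
        base = monoisotopic_mass(formula) * ion.multiplier - (
            monoisotopic_mass(ion.removed) if ion.removed else 0.0
        )
        calcd_text = f"{(base + nominal_mass(ion.added)) / az:.4f}"
    elif category == DiagnosisCategory.MOLECULAR_WEIGHT:
        printed_formula = neutral
        calcd_text = f"{average_mass(ion_formula) / az:.4f}"
        found_text = calcd_text  # the misleadingly validated case
    elif category in (
        DiagnosisCategory.TRANSPOSED_DIGITS,
        DiagnosisCategory.SUBSTITUTED_DIGIT,
    ):
        corrupted = _corrupt_number(
            calcd_text, category, true_ref, formula=ion_formula, ion=ion, rng=rng
        )
        if corrupted is None:
            return None
        calcd_text = corrupted
    elif category == DiagnosisCategory.FORMULA_EDIT:
        label, counts = _EDIT_CHOICES[rng.randrange(len(_EDIT_CHOICES))]
        try:
            # correction "+X" means the printed formula lacks X
            printed = (
                ion_formula.subtract(counts)
                if label.startswith("+")
                else ion_formula.add(counts)
            )
        except FormulaError:
            return None
        if not printed.counts:
            return None
        if _collides(true_ref, _candidate_values(printed, ion)):
            return None
        printed_formula = printed.hill()
        edit_label = label
    elif category == DiagnosisCategory.MALFORMED:
        dialect, template = _MALFORMED_TEMPLATE
        found_text = ""
    else:
        raise ValueError(f"category {category} is not injectable")

    sentence = template.format(
        ion=_ion_label_text(ion, rng),
        formula=printed_formula,
        calcd=calcd_text,
        found=found_text,
    )
    entry = LedgerEntry(
        record_id=record_id,
        file="",
        page=0,
        seq=0,
        category=category,
        dialect=dialect,
        printed_formula=printed_formula,
        true_formula=ion_formula.hill(),
        ion_label=ion.label(),
        true_calcd=round(true_ref, 4),
        printed_calcd=calcd_text,
        printed_found=found_text,
        edit=edit_label,
    )
    return sentence, entry


def _corrupt_number(
    text: str,
    category: DiagnosisCategory,
    true_ref: float,
    formula: Formula,
    ion: IonSpecies,
    rng: random.Random,
) -> Optional[str]:
    """Apply one typing slip to ``text`` such that the slip is uniquely
    recoverable and mimics no other hypothesis."""
    candidates = _candidate_values(formula, ion)
    cfg = DiagnosticConfig()
    positions = list(range(len(text)))
    rng.shuffle(positions)
    if category == DiagnosisCategory.TRANSPOSED_DIGITS:
        for i in positions:
            if i + 1 >= len(text) or not (text[i].isdigit() and text[i + 1].isdigit()):
                continue
            if text[i] == text[i + 1]:
                continue
            variant = text[:i] + text[i + 1] + text[i] + text[i + 2:]
            if _collides(float(variant), candidates):
                continue
            hit = search_digit_typos(variant, true_ref, cfg)
            if hit == (text, "transposition"):
                return variant
        return None
    # substitution: keep |delta| >= 0.01 so the slip is visible above tolerance
    dot = text.index(".")
    for i in positions:
        if not text[i].isdigit() or i > dot + 2:
            continue
        digits = [d for d in "0123456789" if d != text[i]]
        rng.shuffle(digits)
        for d in digits:
            if i == 0 and d == "0":
                continue
            variant = text[:i] + d + text[i + 1:]
            if _collides(float(variant), candidates):
                continue
            hit = search_digit_typos(variant, true_ref, cfg)
            if hit == (text, "substitution"):
                return variant
    return None


def write_corpus(fixture: CorpusFixture, folder: str | Path) -> Path:
    """Write the fixture documents plus a ``ledger.csv`` into ``folder``."""
    import csv

    root = Path(folder)
    root.mkdir(parents=True, exist_ok=True)
    for name, text in fixture.documents.items():
        (root / name).write_text(text, encoding="utf-8")
    with open(root / "ledger.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "record_id",
                "file",
                "page",
                "seq",
                "category",
                "dialect",
                "printed_formula",
                "true_formula",
                "ion_label",
                "true_calcd",
                "printed_calcd",
                "printed_found",
                "edit",
            ]
        )
        for e in fixture.ledger:
            writer.writerow(
                [
                    e.record_id,
                    e.file,
                    e.page,
                    e.seq,
                    e.category.value,
                    e.dialect,
                    e.printed_formula,
                    e.true_formula,
                    e.ion_label,
                    f"{e.true_calcd:.4f}",
                    e.printed_calcd,
                    e.printed_found,
                    e.edit or "",
                ]
            )
    return root
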