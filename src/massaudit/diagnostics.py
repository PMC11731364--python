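"""Recalculate, compare and classify accurate-mass records.

For each extracted quadruplet (formula, ion, calcd, found) the engine
recomputes the ion m/z from first principles and tests a fixed priority list
of hypotheses about how the printed "Calcd" value was produced:

1. consistent with the electron-corrected monoisotopic ion mass;
2. consistent but the found mass deviates beyond the ppm threshold;
3. computed for the neutral species (electron mass not removed/added);
4. computed with the adduct atoms missing from the printed formula;
5. computed with the *nominal* mass of the adduct atom (23.0000 for Na,
   1.0000 for H) instead of its isotopic mass;
6. computed from the average mass (molecular weight) instead of the
   monoisotopic mass;
7. explicable as a typing slip — two adjacent digits transposed, or one
   digit substituted — in the printed number;
8. explicable by a small edit to the molecular formula (a missing or extra
   H, Na, O, C, CH2, F or Cl);
9. otherwise unexplained.

The first matching hypothesis wins, with one refinement: the electron-
corrected and uncorrected candidates for a given reporting convention differ
by only ~0.000549 Da, which can sit inside the match tolerance, so when both
match the *closer* one decides (ties go to consistent).  Without this rule
the consistent hypothesis would absorb every neutral-frame miscalculation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .extraction import MALFORMED_FLAG, AMMRecord, normalize_ion_label
from .masses import (
    ELECTRON_MASS,
    Formula,
    FormulaError,
    IonSpecies,
    monoisotopic_mass,
    average_mass,
    nominal_mass,
    parse_formula,
    ppm_deviation,
)

__all__ = [
    "DiagnosisCategory",
    "DiagnosticConfig",
    "Diagnosis",
    "classify",
    "check_electron_only",
    "check_nominal_adduct",
    "check_molecular_weight",
    "search_digit_typos",
    "search_formula_edits",
    "EDIT_VOCABULARY",
]


class DiagnosisCategory(str, enum.Enum):
    """Primary verdict for one accurate-mass record."""

    CONSISTENT = "CONSISTENT"
    THRESHOLD_EXCEEDED = "THRESHOLD_EXCEEDED"
    ELECTRON_MASS = "ELECTRON_MASS"
    ADDUCT_OMITTED = "ADDUCT_OMITTED"
    NOMINAL_MASS_ADDUCT = "NOMINAL_MASS_ADDUCT"
    MOLECULAR_WEIGHT = "MOLECULAR_WEIGHT"
    FORMULA_EDIT = "FORMULA_EDIT"
    TRANSPOSED_DIGITS = "TRANSPOSED_DIGITS"
    SUBSTITUTED_DIGIT = "SUBSTITUTED_DIGIT"
    MALFORMED = "MALFORMED"
    UNEXPLAINED = "UNEXPLAINED"


#: Formula-edit search space, in priority order.  The sign is the direction
#: of the *correction*: "+H" means the printed formula is one H short and the
#: suggestion adds it ("one H atom added").
EDIT_VOCABULARY: tuple[tuple[str, Mapping[str, int]], ...] = tuple(
    (sign + name, counts)
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


@dataclass(frozen=True)
class DiagnosticConfig:
    """Tunable thresholds of the diagnostic engine.

    ``ppm_threshold`` is the journal-style acceptance limit on the deviation
    between found and calculated masses (default 10 ppm; tolerated deviations
    vary between journals).  ``match_tolerance`` decides when two *calculated*
    masses count as the same number: printed masses carry 4 decimal places,
    so half an ULP is 0.00005 Da and the default 0.0006 Da adds slack for
    upstream rounding chains.  ``mw_tolerance`` is the widened window for
    molecular-weight confusion (MW values are conventionally printed to
    2 dp).  ``max_edit_atoms`` bounds the formula-edit search.
    """

    ppm_threshold: float = 10.0
    match_tolerance: float = 0.0006
    mw_tolerance: float = 0.01
    max_edit_atoms: int = 2
    edit_vocabulary: tuple[tuple[str, Mapping[str, int]], ...] = EDIT_VOCABULARY

    def __post_init__(self) -> None:
        if self.ppm_threshold <= 0:
            raise ValueError("ppm_threshold must be positive")
        if not (0 < self.match_tolerance < 0.01):
            raise ValueError("match_tolerance must lie in (0, 0.01)")

    @classmethod
    def from_file(cls, path: str | Path) -> "DiagnosticConfig":
        """Read ``key = value`` overrides from a plain config file."""
        kwargs: dict[str, float | int] = {}
        casts = {
            "ppm_threshold": float,
            "match_tolerance": float,
            "mw_tolerance": float,
            "max_edit_atoms": int,
        }
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)


@dataclass(frozen=True)
class Diagnosis:
    """Verdict for one record: category, recomputed masses, ppm deviations,
    an optional suggested correction and a one-line explanation."""

    category: DiagnosisCategory
    recalculated_mass: Optional[float] = None
    ppm_calcd_vs_found: Optional[float] = None
    ppm_recalc_vs_found: Optional[float] = None
    suggestion: Optional[str] = None
    explanation: str = ""
    edit: Optional[str] = None


def _fmt(m: float) -> str:
    return f"{m:.4f}"


def _within(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol


@dataclass(frozen=True)
class _IonFrame:
    """Candidate reference masses for one record under both reporting
    conventions (formula names the full ion vs the neutral molecule)."""

    formula: Formula
    ion: IonSpecies
    ref_incl: float
    unc_incl: float
    ion_counts_excl: Optional[Formula] = None
    ref_excl: Optional[float] = None
    unc_excl: Optional[float] = None


def _build_frame(formula: Formula, ion: IonSpecies) -> _IonFrame:
    az = abs(ion.charge)
    mono = monoisotopic_mass(formula)
    ref_incl = (mono - ion.charge * ELECTRON_MASS) / az
    unc_incl = mono / az
    ion_counts = ref_excl = unc_excl = None
    if ion.added or ion.removed or ion.multiplier != 1:
        try:
            ion_counts = ion.ion_counts(formula)
        except FormulaError:
            ion_counts = None  # e.g. [M - H]- from a hydrogen-free formula
        if ion_counts is not None:
            m2 = monoisotopic_mass(ion_counts)
            ref_excl = (m2 - ion.charge * ELECTRON_MASS) / az
            unc_excl = m2 / az
    return _IonFrame(formula, ion, ref_incl, unc_incl, ion_counts, ref_excl, unc_excl)


def _closest_convention(
    calcd: float, ref: float, unc: float, tol: float
) -> Optional[str]:
    """Resolve electron-corrected vs uncorrected candidates by closeness."""
    d_ref, d_unc = abs(calcd - ref), abs(calcd - unc)
    ok_ref, ok_unc = d_ref <= tol, d_unc <= tol
    if ok_ref and ok_unc:
        return "ref" if d_ref <= d_unc else "unc"
    if ok_ref:
        return "ref"
    if ok_unc:
        return "unc"
    return None


def check_electron_only(
    calcd: float, frame: _IonFrame, config: DiagnosticConfig
) -> Optional[str]:
    """Did the calcd value forget the electron-mass correction?

    Returns the matching convention ("incl" or "excl") or ``None``.  A match
    means calcd equals the *neutral-frame* ion mass, off from the true m/z by
    z times the electron mass (0.000549 Da per charge).
    """
    tol = config.match_tolerance
    if _closest_convention(calcd, frame.ref_incl, frame.unc_incl, tol) == "unc":
        return "incl"
    if frame.ref_excl is not None:
        if _closest_convention(calcd, frame.ref_excl, frame.unc_excl, tol) == "unc":
            return "excl"
    return None


def check_nominal_adduct(
    calcd: float, frame: _IonFrame, config: DiagnosticConfig
) -> Optional[tuple[str, float]]:
    """Was the adduct added at its nominal (integer) mass?

    Covers both reporting conventions and both electron conventions; returns
    the adduct description and the mass offset incurred (e.g. +0.0102 Da for
    Na added as 23.0000 instead of 22.9898), or ``None``.
    """
    ion = frame.ion
    if not ion.added:
        return None
    az = abs(ion.charge)
    nominal_added = float(nominal_mass(ion.added))
    exact_added = monoisotopic_mass(ion.added)
    bases: list[float] = []
    # neutral-convention core: printed formula is the molecule
    base = (
        monoisotopic_mass(frame.formula) * ion.multiplier
        - (monoisotopic_mass(ion.removed) if ion.removed else 0.0)
    )
    bases.append(base)
    # ion-convention core: printed formula already contains the adduct atoms
    if frame.formula.contains(ion.added):
        try:
            core = frame.formula.subtract(ion.added)
        except FormulaError:
            core = None
        if core is not None:
            bases.append(
                monoisotopic_mass(core)
                - (monoisotopic_mass(ion.removed) if ion.removed else 0.0)
            )
    for b in bases:
        cand = (b + nominal_added) / az
        cand_e = (b + nominal_added - ion.charge * ELECTRON_MASS) / az
        if _within(calcd, cand, config.match_tolerance) or _within(
            calcd, cand_e, config.match_tolerance
        ):
            label = "".join(
                f"{el}{n if n > 1 else ''}" for el, n in sorted(ion.added.items())
            )
            return label, (nominal_added - exact_added) / az
    return None


def check_molecular_weight(
    calcd: float, frame: _IonFrame, config: DiagnosticConfig
) -> Optional[tuple[float, float]]:
    """Was the average mass (molecular weight) used instead of the exact mass?

    Matched inside the widened ``mw_tolerance`` window; returns the matching
    average-mass analogue together with the correct monoisotopic reference
    under the same convention, or ``None``.  Fires even when the found mass agrees
    with the printed calcd (the "misleadingly validated" case) because the
    monoisotopic recalculation still disagrees.
    """
    az = abs(frame.ion.charge)
    candidates = [(average_mass(frame.formula) / az, frame.ref_incl)]
    if frame.ion_counts_excl is not None:
        candidates.append((average_mass(frame.ion_counts_excl) / az, frame.ref_excl))
    for cand, reference in candidates:
        if _within(calcd, cand, config.mw_tolerance):
            return cand, reference
    return None


def search_digit_typos(
    number_text: str, target: float, config: DiagnosticConfig
) -> Optional[tuple[str, str]]:
    """Find the unique single typing slip that reconciles a printed number.

    Enumerates all adjacent-digit transpositions and all single-digit
    substitutions of ``number_text`` and returns ``(corrected, kind)`` where
    ``kind`` is ``"transposition"`` or ``"substitution"`` — but only when
    exactly one distinct variant matches ``target`` within the match
    tolerance.  Multiple matches are ambiguous and yield ``None``.
    """
    s = number_text
    tol = config.match_tolerance
    matches: dict[str, str] = {}
    for i in range(len(s) - 1):
        if s[i].isdigit() and s[i + 1].isdigit() and s[i] != s[i + 1]:
            variant = s[:i] + s[i + 1] + s[i] + s[i + 2:]
            if _within(float(variant), target, tol):
                matches.setdefault(variant, "transposition")
    for i, ch in enumerate(s):
        if not ch.isdigit():
            continue
        for d in "0123456789":
            if d == ch:
                continue
            variant = s[:i] + d + s[i + 1:]
            if _within(float(variant), target, tol):
                matches.setdefault(variant, "substitution")
    if len(matches) != 1:
        return None
    [(variant, kind)] = matches.items()
    return variant, kind


def search_formula_edits(
    formula: Formula,
    ion: IonSpecies,
    calcd: float,
    found: Optional[float],
    config: DiagnosticConfig,
) -> Optional[tuple[str, Formula, str]]:
    """Find the first vocabulary edit reconciling the formula with the masses.

    Edits are tried in the fixed vocabulary order (±H, ±2H, ±Na, ±O, ±2O,
    ±C, ±CH2, ±F, ±Cl); an edit matches when the edited formula's ion mass
    equals calcd within the match tolerance and, when a found mass exists,
    keeps |ppm vs found| inside the threshold.  An "edit" whose resulting ion
    has the same elemental composition as the record's own ion (e.g. removing
    Na from a formula measured as [M + Na]+ and re-applying the adduct) is a
    reporting-convention restatement, not a formula error, and is skipped.
    Returns ``(edit_label, edited_formula, convention)`` or ``None``.
    """
    own_compositions = [dict(formula.counts)]
    try:
        own_compositions.append(dict(ion.ion_counts(formula).counts))
    except FormulaError:
        pass
    for label, counts in config.edit_vocabulary:
        if max(counts.values()) > config.max_edit_atoms:
            continue
        try:
            if label.startswith("+"):
                edited = formula.add(counts)
            else:
                edited = formula.subtract(counts)
        except FormulaError:
            continue
        frame = _build_frame(edited, ion)
        for convention, ref in (("incl", frame.ref_incl), ("excl", frame.ref_excl)):
            if ref is None:
                continue
            composition = (
                dict(edited.counts)
                if convention == "incl"
                else dict(frame.ion_counts_excl.counts)
            )
            if composition in own_compositions:
                continue
            if not _within(calcd, ref, config.match_tolerance):
                continue
            if found is not None and abs(ppm_deviation(found, ref)) > config.ppm_threshold:
                continue
            return label, edited, convention
    return None


def _parse_number(text: str) -> Optional[float]:
    try:
        return float(text)
    except (TypeError, ValueError):
        return None


def classify(record: AMMRecord, config: DiagnosticConfig | None = None) -> Diagnosis:
    """Assign exactly one primary category to an extracted record.

    Hypotheses are tested in fixed priority order (see module docstring);
    the first match wins.  Unparseable or incomplete records are MALFORMED,
    never dropped.  The reported ``recalculated_mass`` is the electron-
    corrected monoisotopic ion m/z under the reporting convention the
    classifier settled on.
    """
    config = config or DiagnosticConfig()
    tol = config.match_tolerance
    thr = config.ppm_threshold

    formula = ion = None
    parse_problems: list[str] = []
    try:
        formula = parse_formula(record.formula_text)
    except FormulaError as exc:
        parse_problems.append(str(exc))
    try:
        ion = normalize_ion_label(record.ion_text)
    except FormulaError as exc:
        parse_problems.append(str(exc))

    calcd = _parse_number(record.calcd_text)
    found = _parse_number(record.found_text)

    frame = _build_frame(formula, ion) if formula and ion else None
    recalc = frame.ref_incl if frame else None

    def _ppms(reference: Optional[float]) -> tuple[Optional[float], Optional[float]]:
        p_cf = ppm_deviation(found, calcd) if found and calcd else None
        p_rf = ppm_deviation(found, reference) if found and reference else None
        return p_cf, p_rf

    if parse_problems or MALFORMED_FLAG in record.flags or calcd is None or found is None:
        reasons = list(parse_problems)
        if calcd is None:
            reasons.append("calculated mass missing or unreadable")
        if found is None:
            reasons.append("found mass missing or unreadable")
        p_cf, p_rf = _ppms(recalc)
        return Diagnosis(
            DiagnosisCategory.MALFORMED,
            recalculated_mass=recalc,
            ppm_calcd_vs_found=p_cf,
            ppm_recalc_vs_found=p_rf,
            explanation="; ".join(reasons) or "incomplete record",
        )

    assert frame is not None and recalc is not None

    # hypotheses 1-4: reporting convention and electron bookkeeping
    incl = _closest_convention(calcd, frame.ref_incl, frame.unc_incl, tol)
    excl = (
        _closest_convention(calcd, frame.ref_excl, frame.unc_excl, tol)
        if frame.ref_excl is not None
        else None
    )
    if incl == "ref":
        p_cf, p_rf = _ppms(frame.ref_incl)
        if abs(p_cf) <= thr and abs(p_rf) <= thr:
            return Diagnosis(
                DiagnosisCategory.CONSISTENT,
                recalc,
                p_cf,
                p_rf,
                explanation="calcd matches recalculated ion mass; found within threshold",
            )
        return Diagnosis(
            DiagnosisCategory.THRESHOLD_EXCEEDED,
            recalc,
            p_cf,
            p_rf,
            explanation=(
                f"calcd is correct but found deviates {p_cf:+.2f} ppm "
                f"(threshold {thr:g} ppm)"
            ),
        )
    if incl == "unc" or excl == "unc":
        reference = frame.ref_incl if incl == "unc" else frame.ref_excl
        p_cf, p_rf = _ppms(reference)
        note = "" if incl == "unc" else "; adduct atoms also absent from the formula"
        z = frame.ion.charge
        return Diagnosis(
            DiagnosisCategory.ELECTRON_MASS,
            reference,
            p_cf,
            p_rf,
            suggestion=_fmt(reference),
            explanation=(
                f"calcd was computed for the neutral species; the measured ion "
                f"differs by {abs(z)} electron mass ({-z * ELECTRON_MASS:+.6f} Da)"
                + note
            ),
        )
    if excl == "ref":
        assert frame.ion_counts_excl is not None
        suggestion = frame.ion_counts_excl.hill()
        p_cf, p_rf = _ppms(frame.ref_excl)
        return Diagnosis(
            DiagnosisCategory.ADDUCT_OMITTED,
            frame.ref_excl,
            p_cf,
            p_rf,
            suggestion=suggestion,
            explanation=(
                f"adduct atoms of {frame.ion.label()} are not included in the "
                f"formula; the full ion formula is {suggestion}"
            ),
        )

    # hypothesis 5: nominal adduct mass
    nominal = check_nominal_adduct(calcd, frame, config)
    if nominal is not None:
        label, offset = nominal
        reference = frame.ref_excl if frame.ref_excl is not None else frame.ref_incl
        p_cf, p_rf = _ppms(reference)
        return Diagnosis(
            DiagnosisCategory.NOMINAL_MASS_ADDUCT,
            reference,
            p_cf,
            p_rf,
            suggestion=_fmt(reference),
            explanation=(
                f"nominal mass of {label} was added instead of its isotopic "
                f"mass (offset {offset:+.4f} Da); correct calcd is {_fmt(reference)}"
            ),
        )

    # hypothesis 6: molecular weight instead of monoisotopic mass
    mw = check_molecular_weight(calcd, frame, config)
    if mw is not None:
        mw_value, reference = mw
        p_cf, p_rf = _ppms(reference)
        return Diagnosis(
            DiagnosisCategory.MOLECULAR_WEIGHT,
            reference,
            p_cf,
            p_rf,
            suggestion=_fmt(reference),
            explanation=(
                f"calcd matches the molecular weight ({mw_value:.2f}); the "
                f"monoisotopic ion mass is {_fmt(reference)}"
            ),
        )

    # hypothesis 7: typing slips in the printed numbers
    targets = [frame.ref_incl] + ([frame.ref_excl] if frame.ref_excl is not None else [])
    for target in targets:
        hit = search_digit_typos(record.calcd_text, target, config)
        if hit is not None:
            corrected, kind = hit
            category = (
                DiagnosisCategory.TRANSPOSED_DIGITS
                if kind == "transposition"
                else DiagnosisCategory.SUBSTITUTED_DIGIT
            )
            p_cf, p_rf = _ppms(target)
            return Diagnosis(
                category,
                target,
                p_cf,
                p_rf,
                suggestion=corrected,
                explanation=f"calcd {record.calcd_text} is a {kind} of {corrected}",
            )
    for target in targets:
        hit = search_digit_typos(record.found_text, target, config)
        if hit is not None:
            corrected, kind = hit
            category = (
                DiagnosisCategory.TRANSPOSED_DIGITS
                if kind == "transposition"
                else DiagnosisCategory.SUBSTITUTED_DIGIT
            )
            p_cf, p_rf = _ppms(target)
            return Diagnosis(
                category,
                target,
                p_cf,
                p_rf,
                suggestion=corrected,
                explanation=f"found {record.found_text} is a {kind} of {corrected}",
            )

    # hypothesis 8: bounded formula edit
    edit_hit = search_formula_edits(formula, ion, calcd, found, config)
    if edit_hit is not None:
        label, edited, convention = edit_hit
        edited_frame = _build_frame(edited, ion)
        reference = (
            edited_frame.ref_incl if convention == "incl" else edited_frame.ref_excl
        )
        p_cf, p_rf = _ppms(reference)
        words = {"+": "added to", "-": "removed from"}[label[0]]
        return Diagnosis(
            DiagnosisCategory.FORMULA_EDIT,
            reference,
            p_cf,
            p_rf,
            suggestion=edited.hill(),
            edit=label,
            explanation=(
                f"{label[1:]} {words} the printed formula reconciles calcd and "
                f"found; suggested formula {edited.hill()}"
            ),
        )

    p_cf, p_rf = _ppms(recalc)
    return Diagnosis(
        DiagnosisCategory.UNEXPLAINED,
        recalc,
        p_cf,
        p_rf,
        explanation=(
            f"calcd {record.calcd_text} matches no hypothesis; recalculated "
            f"ion mass is {_fmt(recalc)}"
        ),
    )
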