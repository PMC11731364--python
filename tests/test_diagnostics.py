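"""Classification of accurate-mass records into the error taxonomy."""

import itertools
import random

import pytest

from massaudit.diagnostics import (
    Diagnosis,
    DiagnosisCategory as Cat,
    DiagnosticConfig,
    classify,
    search_digit_typos,
    search_formula_edits,
)
from massaudit.extraction import normalize_ion_label
from massaudit.masses import (
    ELECTRON_MASS,
    Formula,
    IonSpecies,
    monoisotopic_mass,
    parse_formula,
    ppm_deviation,
)


class TestClassifyTaxonomy:
    @pytest.mark.parametrize(
        "formula, ion, calcd, found, expected",
        [
            # the ACS worked example: calcd is right, found is 10.46 ppm off
            ("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1074", Cat.THRESHOLD_EXCEEDED),
            ("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1099", Cat.CONSISTENT),
            # formula printed without the sodium of the measured ion
            ("C13H17NO3", "[M + Na]+", "258.1101", "258.1099", Cat.ADDUCT_OMITTED),
            # calcd in the neutral frame (electron not removed)
            ("C13H17NO3Na", "[M + Na]+", "258.1106", "258.1099", Cat.ELECTRON_MASS),
            # Na added at 23.0000 instead of 22.9898
            ("C13H17NO3", "[M + Na]+", "258.1208", "258.1099", Cat.NOMINAL_MASS_ADDUCT),
            # H added at 1.0000 instead of 1.0078
            ("C13H17NO3", "[M + H]+", "236.1208", "236.1275", Cat.NOMINAL_MASS_ADDUCT),
            # molecular weight used, and "validated" by a matching found value
            ("C13H17NO3", "[M + H]+", "236.29", "236.29", Cat.MOLECULAR_WEIGHT),
            ("C13H17NO3Na", "[M + Na]+", "258.1011", "258.1099", Cat.TRANSPOSED_DIGITS),
            ("C13H17NO3Na", "[M + Na]+", "248.1101", "248.1099", Cat.SUBSTITUTED_DIGIT),
            ("C13H16NO3Na", "[M + Na]+", "258.1101", "258.1099", Cat.FORMULA_EDIT),
            ("C13H17NO3Na", "[M + Na]+", "259.9999", "258.1099", Cat.UNEXPLAINED),
            # negative mode: correct deprotonated reference adds m_e
            ("C9H7O4", "[M - H]-", "179.0350", "179.0352", Cat.CONSISTENT),
        ],
    )
    def test_primary_category(self, make_record, config, formula, ion, calcd, found, expected):
        d = classify(make_record(formula, ion, calcd, found), config)
        assert d.category is expected

    def test_threshold_case_ppm_value(self, make_record, config):
        d = classify(make_record("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1074"))
        assert round(d.ppm_calcd_vs_found, 2) == -10.46
        assert round(d.recalculated_mass, 4) == 258.1101

    def test_adduct_omitted_suggests_full_ion_formula(self, make_record, config):
        d = classify(make_record("C13H17NO3", "[M + Na]+", "258.1101", "258.1099"))
        assert parse_formula(d.suggestion).counts == parse_formula("C13H17NO3Na").counts

    def test_unparseable_formula_is_malformed_with_error_text(self, make_record):
        d = classify(make_record("C13Hx17", "[M + H]+", "236.1281", "236.1283"))
        assert d.category is Cat.MALFORMED
        assert "Hx" in d.explanation

    def test_unrecognized_ion_label_is_malformed(self, make_record):
        d = classify(make_record("C13H17NO3", "[Q + H]+", "236.1281", "236.1283"))
        assert d.category is Cat.MALFORMED

    def test_missing_found_is_malformed(self, make_record):
        d = classify(make_record("C13H17NO3Na", "[M + Na]+", "258.1101", ""))
        assert d.category is Cat.MALFORMED
        assert round(d.recalculated_mass, 4) == 258.1101  # still recalculated

    def test_consistent_verdict_is_sound(self, make_record, config):
        d = classify(make_record("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1099"))
        assert abs(d.ppm_recalc_vs_found) <= config.ppm_threshold
        assert abs(float("258.1101") - d.recalculated_mass) <= config.match_tolerance

    def test_stricter_threshold_reclassifies(self, make_record):
        strict = DiagnosticConfig(ppm_threshold=0.5)
        d = classify(make_record("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1099"), strict)
        assert d.category is Cat.THRESHOLD_EXCEEDED

    def test_priority_stable_under_record_order(self, make_record, config):
        rows = [
            ("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1074"),
            ("C13H17NO3", "[M + Na]+", "258.1101", "258.1099"),
            ("C13H17NO3Na", "[M + Na]+", "258.1106", "258.1099"),
            ("C13H16NO3Na", "[M + Na]+", "258.1101", "258.1099"),
        ]
        records = [make_record(*r) for r in rows]
        baseline = {r: classify(r, config) for r in records}
        rng = random.Random(0)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            for r in shuffled:
                assert classify(r, config) == baseline[r]


class TestElectronMass:
    def test_singly_charged_neutral_frame_match(self, make_record):
        d = classify(make_record("C13H17NO3Na", "[M + Na]+", "258.1106", "258.1099"))
        assert d.category is Cat.ELECTRON_MASS
        assert d.suggestion == "258.1101"

    def test_correct_calcd_is_not_electron_flagged(self, make_record):
        d = classify(make_record("C13H17NO3Na", "[M + Na]+", "258.1101", "258.1099"))
        assert d.category is Cat.CONSISTENT

    def test_doubly_charged_gap_of_two_electron_masses(self, make_record):
        f = parse_formula("C22H32N6O4S")  # sildenafil + 2H
        mz_true = (monoisotopic_mass(f) - 2 * ELECTRON_MASS) / 2
        mz_neutral = monoisotopic_mass(f) / 2
        d = classify(
            make_record("C22H32N6O4S", "[M + 2H]2+", f"{mz_neutral:.4f}", f"{mz_true:.4f}")
        )
        assert d.category is Cat.ELECTRON_MASS

    def test_discrimination_down_the_mass_range(self, make_record):
        # m_e stays 0.000549 Da at any mass, well above 4-dp rounding noise;
        # check the neutral-frame value still separates cleanly near 600 Da
        f = parse_formula("C33H36FN2O5")  # atorvastatin + H, ~ 559.26
        mz = monoisotopic_mass(f) - ELECTRON_MASS
        good = classify(make_record("C33H36FN2O5", "[M + H]+", f"{mz:.4f}", f"{mz:.4f}"))
        bad = classify(
            make_record("C33H36FN2O5", "[M + H]+", f"{mz + ELECTRON_MASS:.4f}", f"{mz:.4f}")
        )
        assert good.category is Cat.CONSISTENT
        assert bad.category is Cat.ELECTRON_MASS


class TestNominalAdduct:
    def test_sodium_offset(self, make_record):
        d = classify(make_record("C13H17NO3", "[M + Na]+", "258.1208", "258.1099"))
        assert d.category is Cat.NOMINAL_MASS_ADDUCT
        assert "+0.0102" in d.explanation

    def test_proton_offset(self, make_record):
        d = classify(make_record("C13H17NO3", "[M + H]+", "236.1208", "236.1275"))
        assert d.category is Cat.NOMINAL_MASS_ADDUCT
        assert "-0.0078" in d.explanation

    def test_correct_calcd_no_match(self, make_record):
        d = classify(make_record("C13H17NO3", "[M + H]+", "236.1281", "236.1283"))
        assert d.category is not Cat.NOMINAL_MASS_ADDUCT


class TestMolecularWeight:
    def test_mw_flagged_despite_matching_found(self, make_record):
        d = classify(make_record("C13H17NO3", "[M + H]+", "236.29", "236.29"))
        assert d.category is Cat.MOLECULAR_WEIGHT
        assert abs(ppm_deviation(236.29, d.recalculated_mass)) > 600

    def test_monoisotopic_element_formula_not_flagged(self, make_record):
        # NaI: both elements monoisotopic, MW == exact mass; a correct calcd
        # must stay consistent rather than be "MW-flagged"
        f = parse_formula("NaI")
        mz = monoisotopic_mass(f.add({"Na": 1})) - ELECTRON_MASS
        d = classify(make_record("NaINa", "[M + Na]+", f"{mz:.4f}", f"{mz:.4f}"))
        assert d.category is Cat.CONSISTENT


class TestDigitTypos:
    def _brute_variants(self, s):
        """Independent enumeration of every single slip of the string."""
        out = set()
        for i in range(len(s) - 1):
            if s[i].isdigit() and s[i + 1].isdigit():
                out.add(s[:i] + s[i + 1] + s[i] + s[i + 2:])
        for i, ch in enumerate(s):
            if ch.isdigit():
                for d in "0123456789":
                    out.add(s[:i] + d + s[i + 1:])
        out.discard(s)
        return out

    @pytest.mark.parametrize(
        "text, target, corrected, kind",
        [
            ("258.1011", 258.1101, "258.1101", "transposition"),
            ("248.1101", 258.1101, "258.1101", "substitution"),
            ("185.0506", 181.0506, "181.0506", "substitution"),
        ],
    )
    def test_unique_slip_found(self, config, text, target, corrected, kind):
        assert search_digit_typos(text, target, config) == (corrected, kind)
        # oracle: exactly one enumerated variant matches the target
        close = [
            v
            for v in self._brute_variants(text)
            if abs(float(v) - target) <= config.match_tolerance
        ]
        assert close == [corrected]

    def test_exact_number_needs_no_typo(self, config):
        assert search_digit_typos("258.1101", 258.1101, config) is None

    def test_ambiguous_matches_return_none(self, config):
        # wide tolerance makes several last-digit substitutions match
        loose = DiagnosticConfig(match_tolerance=0.005)
        assert search_digit_typos("258.1101", 258.1140, loose) is None


class TestFormulaEdits:
    @pytest.mark.parametrize(
        "printed, true, adduct", [
            ("C13H16NO3Na", "C13H17NO3Na", "Na"),  # one H short     -> +H
            ("C13H17NO2Na", "C13H17NO3Na", "Na"),  # one O short     -> +O
            ("C13H18NO3", "C13H18NO3Na", "H"),     # sodium missing  -> +Na
            ("C14H19NO3Na", "C13H17NO3Na", "Na"),  # extra CH2       -> -CH2
            ("C13H19NO3Na", "C13H17NO3Na", "Na"),  # two extra H     -> -2H
        ],
    )
    def test_edit_recovers_true_formula(self, config, printed, true, adduct):
        ion = IonSpecies(added={adduct: 1}, charge=1)
        f_true = parse_formula(true)
        calcd = (monoisotopic_mass(f_true) - ELECTRON_MASS)
        hit = search_formula_edits(
            parse_formula(printed), ion, calcd, calcd + 1e-4, config
        )
        assert hit is not None
        _, edited, _ = hit
        assert edited.counts == f_true.counts

    def test_correct_formula_proposes_no_edit(self, config):
        f = parse_formula("C13H17NO3Na")
        ion = IonSpecies(added={"Na": 1}, charge=1)
        calcd = monoisotopic_mass(f) - ELECTRON_MASS
        assert search_formula_edits(f, ion, calcd, calcd, config) is None

    def test_agrees_with_brute_force_over_atom_edits(self, config):
        """Oracle: exhaustive search over all signed multisets of up to three
        atoms from {H, C, N, O, Na, F, Cl, S} must confirm every suggestion."""
        elements = ["H", "C", "N", "O", "Na", "F", "Cl", "S"]
        deltas = []
        for r in (1, 2, 3):
            for combo in itertools.combinations_with_replacement(elements, r):
                counts = {}
                for el in combo:
                    counts[el] = counts.get(el, 0) + 1
                deltas.append(counts)

        def brute(formula, ion, calcd, found):
            own = ion.ion_counts(formula).counts
            hits = []
            for counts in deltas:
                for sign in (+1, -1):
                    try:
                        edited = (
                            formula.add(counts) if sign > 0 else formula.subtract(counts)
                        )
                    except Exception:
                        continue
                    if edited.counts == own:
                        continue  # convention restatement, not a formula edit
                    ref = monoisotopic_mass(edited) - ion.charge * ELECTRON_MASS
                    ref /= abs(ion.charge)
                    if (
                        abs(calcd - ref) <= config.match_tolerance
                        and abs(ppm_deviation(found, ref)) <= config.ppm_threshold
                    ):
                        hits.append(frozenset(edited.counts.items()))
            return hits

        rng = random.Random(4)
        pool = [
            "C13H17NO3Na", "C9H9O4", "C17H20FN3O3Na", "C21H27O5", "C29H32N7O",
            "C8H11N4O2", "C22H31N6O4S", "C16H22ClN2O",
        ]
        ion = IonSpecies(added={"Na": 1}, charge=1)
        checked = 0
        for name in pool:
            f_true = parse_formula(name)
            assert f_true.counts.get("C", 0) <= 30
            calcd = monoisotopic_mass(f_true) - ELECTRON_MASS
            found = calcd * (1 + rng.uniform(-3, 3) * 1e-6)
            for label, counts in config.edit_vocabulary:
                try:
                    printed = (
                        f_true.subtract(counts)
                        if label.startswith("+")
                        else f_true.add(counts)
                    )
                except Exception:
                    continue
                hit = search_formula_edits(printed, ion, calcd, found, config)
                brute_hits = brute(printed, ion, calcd, found)
                if hit is None:
                    assert brute_hits == []
                else:
                    _, edited, _ = hit
                    assert frozenset(edited.counts.items()) in brute_hits
                    assert edited.counts == f_true.counts
                    checked += 1
        assert checked >= 30
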