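"""Element masses, molecular-formula handling and ion m/z algebra.

Three distinct mass scales are exposed, because confusing them is the root of
several real-world reporting errors in high-resolution mass spectrometry (HRMS):

* **monoisotopic (exact) mass** — sum of the masses of each element's most
  abundant isotope; the quantity an HRMS "Calcd" value should report,
* **average mass (molecular weight)** — abundance-weighted mean over the
  natural isotopic composition,
* **nominal mass** — integer mass-number sum (H = 1, Na = 23).

Ion m/z values are computed in the *ion frame*: the mass of the electron(s)
gained or lost on ionization is accounted for, so the reference value for
``[M + Na]+`` is ``M + m(Na) - m_e``, not ``M + m(Na)``.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ELECTRON_MASS",
    "ElementRecord",
    "MASS_TABLE",
    "Formula",
    "IonSpecies",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "nominal_mass",
    "ion_mass",
    "ppm_deviation",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909


class FormulaError(ValueError):
    """Raised for unparseable formulas, unknown elements or invalid ion algebra."""


@dataclass(frozen=True)
class ElementRecord:
    """Mass data for one element.

    ``monoisotopic_mass`` is the mass of the most abundant isotope (Da),
    ``average_mass`` the abundance-weighted standard atomic weight (Da) and
    ``nominal_mass`` the mass number of the most abundant isotope.
    """

    symbol: str
    monoisotopic_mass: float
    average_mass: float
    nominal_mass: int


def _table(rows: Iterable[tuple[str, float, float, int]]) -> dict[str, ElementRecord]:
    return {s: ElementRecord(s, mono, avg, nom) for s, mono, avg, nom in rows}


# Monoisotopic masses: NIST Atomic Masses (most abundant isotope).
# Average masses: abundance-weighted over the NIST isotopic composition.
MASS_TABLE: dict[str, ElementRecord] = _table(
    [
        ("H", 1.00782503207, 1.0079407, 1),
        ("B", 11.0093054, 10.8110281, 11),
        ("C", 12.0000000, 12.0107359, 12),
        ("N", 14.0030740048, 14.0067032, 14),
        ("O", 15.9949146196, 15.9994049, 16),
        ("F", 18.99840322, 18.9984032, 19),
        ("Na", 22.9897692809, 22.9897693, 23),
        ("Si", 27.9769265325, 28.0854987, 28),
        ("P", 30.97376163, 30.9737616, 31),
        ("S", 31.97207100, 32.0647872, 32),
        ("Cl", 34.96885268, 35.4529376, 35),
        ("K", 38.96370668, 39.0983011, 39),
        ("Br", 78.9183371, 79.9035280, 79),
        ("I", 126.904473, 126.9044730, 127),
    ]
)

# Unicode typography seen in extracted SI text, mapped to ASCII before parsing.
_TRANSLATE = str.maketrans(
    {
        **{c: str(d) for d, c in enumerate("₀₁₂₃₄₅₆₇₈₉")},
        **{c: str(d) for d, c in enumerate("⁰¹²³⁴⁵⁶⁷⁸⁹")},
        "⁺": "+",
        "⁻": "-",
        "−": "-",  # U+2212 minus
        "–": "-",  # en dash
        "—": "-",  # em dash
        " ": " ",
        " ": " ",
        " ": " ",
        "⁠": "",
        "​": "",
    }
)


def normalize_typography(text: str) -> str:
    """Map Unicode sub/superscripts, minus variants and thin spaces to ASCII."""
    return unicodedata.normalize("NFKC", text.translate(_TRANSLATE))


@dataclass(frozen=True)
class Formula:
    """An element-count multiset with an optional net charge.

    ``counts`` maps element symbols to positive integer counts.  Rendering uses
    Hill order (C first, then H, then remaining symbols alphabetically; fully
    alphabetical when no carbon is present) and round-trips through
    :func:`parse_formula`.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n}
        for el, n in clean.items():
            if n < 1:
                raise FormulaError(f"negative count for element {el!r}")
        object.__setattr__(self, "counts", dict(clean))

    def hill(self) -> str:
        """Render in Hill notation, with a trailing charge token if charged."""
        parts: list[str] = []
        counts = dict(self.counts)
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
        order.extend(sorted(el for el in counts if el not in order))
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        body = "".join(parts)
        if abs(self.charge) == 1:
            body += "+" if self.charge > 0 else "-"
        elif self.charge:
            # superscript magnitude: an ASCII "2+" after an element symbol
            # would read back as a count ("N2+" is N2 with charge +1)
            supers = "⁰¹²³⁴⁵⁶⁷⁸⁹"
            body += supers[abs(self.charge)] + ("⁺" if self.charge > 0 else "⁻")
        return body

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def add(self, other: Mapping[str, int], times: int = 1) -> "Formula":
        merged = Counter(self.counts)
        for el, n in other.items():
            merged[el] += n * times
        return Formula(dict(merged), self.charge)

    def subtract(self, other: Mapping[str, int], times: int = 1) -> "Formula":
        merged = Counter(self.counts)
        for el, n in other.items():
            merged[el] -= n * times
            if merged[el] < 0:
                raise FormulaError(
                    f"cannot remove {n * times} {el} from {self.hill()}"
                )
        return Formula({el: n for el, n in merged.items() if n}, self.charge)

    def scaled(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.counts.items()}, self.charge)

    def contains(self, other: Mapping[str, int]) -> bool:
        return all(self.counts.get(el, 0) >= n for el, n in other.items())


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# A superscript charge carries its magnitude ("²⁺" = 2+); a plain trailing
# +/- is magnitude 1, since an ASCII digit before it is an element count
# ("C17H22BN2+" is N2 with charge +1, not charge 2+).
_SUPER_CHARGE = re.compile(r"([⁰¹²³⁴⁵⁶⁷⁸⁹]?)([⁺⁻])\s*$")
_ASCII_CHARGE = re.compile(r"([+-])\s*$")
_BRACKET_ISOTOPE = re.compile(r"\[\d+[A-Z][a-z]?\]|^\d")


def parse_formula(text: str) -> Formula:
    """Parse a molecular formula string such as ``"C13H17NO3Na"``.

    Typographic sub/superscripts are normalized first; a trailing charge token
    (``+``, ``-``, superscript ``²⁺`` ...) is captured into
    :attr:`Formula.charge`.  Implicit counts of 1 are expanded.
    Deuterium/tritium shorthand and isotope-labelled formulas are rejected.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    raw = text.strip().replace(" ", "")
    charge = 0
    m = _SUPER_CHARGE.search(raw)
    if m:
        mag = int(normalize_typography(m.group(1)) or 1)
        charge = mag if m.group(2) == "⁺" else -mag
        raw = raw[: m.start()]
    s = normalize_typography(raw).replace(" ", "")
    if _BRACKET_ISOTOPE.search(s):
        raise FormulaError(f"isotope labels are not supported: {text!r}")
    if charge == 0:
        m = _ASCII_CHARGE.search(s)
        if m:
            charge = 1 if m.group(1) == "+" else -1
            s = s[: m.start()]
    counts: Counter[str] = Counter()
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"unparseable token at {s[pos:pos + 4]!r} in {text!r}")
        el, num = m.group(1), m.group(2)
        if el in ("D", "T"):
            raise FormulaError(
                f"isotope label {el!r} in {text!r} is not supported"
            )
        if el not in MASS_TABLE:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] += int(num) if num else 1
        pos = m.end()
    if not counts:
        raise FormulaError(f"no element tokens in {text!r}")
    return Formula(dict(counts), charge)


def _mass(counts: Mapping[str, int], attr: str) -> float:
    total = 0.0
    for el, n in counts.items():
        try:
            rec = MASS_TABLE[el]
        except KeyError:
            raise FormulaError(f"element {el!r} not in mass table") from None
        total += n * getattr(rec, attr)
    return total


def monoisotopic_mass(f: Formula | Mapping[str, int]) -> float:
    """Neutral-frame monoisotopic mass in Da (no electron correction)."""
    counts = f.counts if isinstance(f, Formula) else f
    return _mass(counts, "monoisotopic_mass")


def average_mass(f: Formula | Mapping[str, int]) -> float:
    """Average mass (molecular weight) in Da."""
    counts = f.counts if isinstance(f, Formula) else f
    return _mass(counts, "average_mass")


def nominal_mass(f: Formula | Mapping[str, int]) -> int:
    """Integer nominal mass in Da."""
    counts = f.counts if isinstance(f, Formula) else f
    return int(_mass(counts, "nominal_mass"))


@dataclass(frozen=True)
class IonSpecies:
    """An ionization mode ``[nM + added - removed]^z``.

    ``multiplier`` is the ``n`` in ``[nM + Na]+`` (dimer adducts etc.),
    ``added``/``removed`` are atom multisets gained/lost on ionization and
    ``charge`` the signed ion charge.  Only ``|charge| <= 2`` is supported;
    multiply charged species beyond that are rejected explicitly.
    """

    multiplier: int = 1
    added: Mapping[str, int] = field(default_factory=dict)
    removed: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise FormulaError("ion charge must be nonzero")
        if abs(self.charge) > 2:
            raise FormulaError(
                f"charge state {self.charge:+d} not supported (|z| <= 2)"
            )
        if self.multiplier < 1:
            raise FormulaError("ion multiplier must be >= 1")
        object.__setattr__(self, "added", dict(self.added))
        object.__setattr__(self, "removed", dict(self.removed))

    def label(self) -> str:
        """Canonical bracket label, e.g. ``[2M + Na]+``."""
        inner = f"{self.multiplier if self.multiplier > 1 else ''}M"
        for el, n in sorted(self.added.items()):
            inner += f" + {'' if n == 1 else n}{el}"
        for el, n in sorted(self.removed.items()):
            inner += f" - {'' if n == 1 else n}{el}"
        mag = "" if abs(self.charge) == 1 else str(abs(self.charge))
        return f"[{inner}]{mag}{'+' if self.charge > 0 else '-'}"

    def ion_counts(self, f: Formula) -> Formula:
        """Element multiset of the full ion given the neutral molecule ``f``."""
        return f.scaled(self.multiplier).add(self.added).subtract(self.removed)


def ion_mass(
    f: Formula,
    ion: IonSpecies,
    *,
    formula_includes_adduct: bool = False,
    electron_correction: bool = True,
) -> float:
    """Reference m/z of ``ion`` formed from ``f``.

    When ``formula_includes_adduct`` is true the formula already names every
    atom of the ion (the ACS reporting convention) and the adduct algebra is
    not applied again.  ``electron_correction=False`` returns the (incorrect)
    neutral-frame value, used by the diagnostics to recognise calculations
    that forgot the electron.
    """
    if formula_includes_adduct:
        m = monoisotopic_mass(f)
    else:
        m = monoisotopic_mass(ion.ion_counts(f))
    if electron_correction:
        m -= ion.charge * ELECTRON_MASS
    return m / abs(ion.charge)


def ppm_deviation(observed: float, reference: float) -> float:
    """Signed relative deviation ``(observed - reference) / reference`` in ppm."""
    if reference <= 0:
        raise ValueError(f"reference mass must be positive, got {reference}")
    return (observed - reference) / reference * 1e6
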