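# Methods

## The audit model

An HRMS statement in an experimental section asserts four things at once: a
molecular formula, a measured ion species (e.g. `[M + Na]+`), a calculated
m/z and a found m/z. These four values are redundant — the formula and the
ion determine the calculated mass, and the found mass must agree with it to
within an instrument-level tolerance — so internal consistency can be
checked mechanically, with no access to spectra or structures. That is all
this package checks: whether a formula corresponds to the drawn structure is
out of scope by construction.

The reference value for a measured ion is the electron-corrected
monoisotopic m/z

    m/z = (n·M + m(added) − m(removed) − z·m_e) / |z|

where `M` is the monoisotopic mass of the neutral molecule, `n` the ion
multiplier (the 2 in `[2M + Na]+`), `added`/`removed` the adduct atoms,
`z` the signed charge and `m_e = 0.000548579909 Da` the electron mass
(CODATA). For anions the `−z·m_e` term *adds* electron mass. Two reporting
conventions exist for the printed formula: it may name the full ion
(`C13H17NO3Na` for `[M + Na]+`, the ACS convention) or the neutral molecule
(`C13H17NO3`). The engine evaluates both; a correct calcd paired with a
neutral-convention formula is reported as the adduct-omission class, since
the formula does not name the species that was measured.

Monoisotopic masses are the NIST masses of each element's most abundant
isotope (not the lowest-mass isotope; the two coincide for the covered
elements). Average masses are abundance-weighted means over the NIST
isotopic composition — numerically indistinguishable, at the 4-decimal
precision of this domain, from standard atomic weights, and directly
comparable against abundance-based reference implementations. Nominal
masses are the mass numbers of the most abundant isotopes. The element
table covers C, H, N, O, Na, S, P, F, Cl, Br, I, B, Si and K; isotope
labels (D, T, `[13C]`) are rejected explicitly rather than silently
miscomputed.

## Classification

Hypotheses about how a printed calcd value was produced are tested in a
fixed order, most specific first; the first match decides the category:

1. **CONSISTENT / THRESHOLD_EXCEEDED** — calcd equals the electron-corrected
   reference within the match tolerance; the found mass is then inside or
   outside the ppm threshold (against both the printed and the recalculated
   value).
2. **ELECTRON_MASS** — calcd equals the *neutral-frame* value, off by
   `|z|·m_e`.
3. **ADDUCT_OMITTED** — calcd is correct for formula + adduct, but the
   printed formula lacks the adduct atoms; the suggestion is the full ion
   formula.
4. **NOMINAL_MASS_ADDUCT** — calcd matches core + *integer* adduct mass
   (+23.0000 for Na instead of +22.9898, offset +0.0102 Da; +1.0000 for H,
   offset −0.0078 Da), under either reporting and either electron
   convention.
5. **MOLECULAR_WEIGHT** — calcd matches the average-mass analogue within a
   widened 0.01 Da window (MW values are conventionally printed to 2 dp).
   This fires even when the found value agrees with calcd — measurements can
   appear to validate a miscalculation — because the monoisotopic
   recalculation still disagrees.
6. **TRANSPOSED_DIGITS / SUBSTITUTED_DIGIT** — some adjacent-digit swap or
   single-digit replacement of the printed number reproduces the reference;
   accepted only when exactly one enumerated variant matches (ambiguity
   yields no verdict). Tried on calcd first, then on found.
7. **FORMULA_EDIT** — a bounded edit to the formula (±H, ±2H, ±Na, ±O, ±2O,
   ±C, ±CH2, ±F, ±Cl, in that priority) reconciles calcd and found; the
   label names the *correction* ("+H" = one H atom must be added). An edit
   whose resulting ion merely restates the record's own ion under the other
   reporting convention (removing Na from an `[M + Na]+` formula) is not a
   formula error and is excluded.
8. **UNEXPLAINED** otherwise; **MALFORMED** when a field is missing or
   unparseable (the record is kept, never dropped).

**Electron/consistent tie-break.** The default match tolerance (0.0006 Da)
exceeds the electron mass (0.000549 Da), so a neutral-frame calcd matches
*both* the corrected and the uncorrected candidate. Within each reporting
convention the two candidates are therefore resolved by *closest match*
(ties to consistent): a calcd printed at 4 dp sits within half an ULP
(0.00005 Da) of whichever frame produced it, an order of magnitude closer
than the 0.000549 Da to the other frame, so the discrimination is reliable
at any mass where 4-dp printing is in use. Strict first-match priority
without this rule would absorb every electron-mass error into CONSISTENT.

## Parameters

| parameter         | default   | units | meaning |
|-------------------|-----------|-------|---------|
| `ppm_threshold`   | 10        | ppm   | journal-style acceptance limit on found-vs-calcd deviation; journals vary, so it is a flag, not a verdict of wrongness |
| `match_tolerance` | 0.0006    | Da    | when two calculated masses count as "the same number": half an ULP of 4-dp printing (0.00005) plus slack for upstream rounding chains |
| `mw_tolerance`    | 0.01      | Da    | widened window for molecular-weight confusion (MW printed to 2 dp) |
| `max_edit_atoms`  | 2         | atoms | per-element cap on the formula-edit search |

All masses are reported at 4 decimal places (round half-even) and ppm
deviations at 2, matching SI convention and making reports byte-reproducible.
Charge states up to |z| = 2 are supported; higher charges are rejected with
a clear error, as they do not occur in small-molecule SI reporting.

## Extraction grammar

The HRMS statement grammar is table-driven: anchors (`HRMS`, `HR-MS`,
`HRESIMS`, …), "calculated" spellings (`Calcd`, `calcd.`, `calc'd`,
`Calculated`), "found" spellings and dialect orderings (ion label before or
after `Calcd for`) are data, so new dialects are added without code changes.
Masses must carry 3–5 decimal places (integers are rejected to avoid
matching figure or compound numbers), and both numbers must begin within
120 characters of the anchor to prevent cross-sentence capture. A statement
with a missing calcd or found number is emitted with a `MALFORMED` flag
rather than dropped. Page text is normalized first: end-of-line hyphenation
joined, line breaks collapsed, Unicode minus signs, thin spaces and
sub/superscripts mapped to ASCII.

PDF reading is a pluggable thin layer behind `extract_page_text`: `.txt`
documents (form-feed page separator) are always supported, `.pdf` goes
through `pypdf` when importable, and unreadable, encrypted or unsupported
files are skipped with a logged warning — robustness over a large corpus is
the design goal, so findings are data and extraction failures are warnings,
never crashes.

## The synthetic corpus generator

Real SI corpora are not redistributable, so the test bed is generated. Each
record draws a formula from a pool of 50 real drug-like compositions
(CHNOS with F and Cl, monoisotopic 150–800 Da) and an ion from
`[M + H]+` (50%), `[M + Na]+` (35%), `[M − H]−` (15%); the true calcd/found
pair is computed from first principles with the found value jittered
uniformly within ±5 ppm — below the 10 ppm threshold, so the injected error
class and not noise determines the diagnosis — and exactly one corruption is
applied. Threshold-exceedance records place the found value at 15–40 ppm,
safely beyond the flag boundary. The default mix leaves 40% of records
fully consistent, echoing the share of real SI files that passes such an
audit untouched, and spreads the remainder over all nine injectable error
classes.

Constructions are kept unambiguous: a corruption whose value lands within
1.5× tolerance of a *different* hypothesis for that record (a +0.01 digit
substitution mimicking a nominal-mass Na addition, say) is redrawn, as is a
category not injectable for the drawn formula/ion (nominal-mass injection
needs an added atom). Typo corruptions are verified uniquely recoverable by
the same enumeration the classifier uses. The generator is deterministic in
its seed; every emitted record appears exactly once in the ground-truth
ledger.

What the generator does **not** emulate: PDF layout artifacts and OCR noise,
unusual or malformed dialects outside the grammar table, compound errors
(two mistakes in one record), multiply charged or exotic adducts, and the
long tail of free-text variation in real SI files. Passing round-trip tests
therefore demonstrates the engine's arithmetic and taxonomy are correct
under clean extraction, not that extraction recall on arbitrary real PDFs
is complete.

## Problem sizes and verification

The round-trip acceptance check uses a 1000-record corpus (50 documents,
4 pages each) spanning all injectable categories; it runs in about a second.
Mass calculators are cross-checked against an independent NIST-based
reference implementation (pyteomics) to 1e-4 Da over the 50-formula pool,
and the edit search against a brute-force enumeration over all signed atom
multisets of up to three atoms. Reports are verified byte-identical across
reruns on identical inputs.

## Known limitations

- Isotope-labelled compounds (common in mechanistic SI sections) are
  rejected at the parser, so their records surface as MALFORMED.
- A typo in the found value of a record whose calcd is correct is reported
  as THRESHOLD_EXCEEDED (the higher-priority verdict); typo recovery on
  found values runs only when calcd itself is off, where it is rarely
  unambiguous.
- The electron/consistent discrimination presumes 4-dp printing; values
  printed at 3 dp carry rounding noise of the same order as the electron
  mass and can be resolved either way.
- The `>99%` extraction recall holds on the generator's dialects; real
  journals contain dialects outside the table, which must be added as data.
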