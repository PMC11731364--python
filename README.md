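# massaudit

Automated auditing of accurate-mass (HRMS) data in chemistry Supporting
Information.

Every HRMS statement in an experimental section —

> HRMS (ESI/Q-TOF) m/z: [M + Na]+ Calcd for C13H17NO3Na 258.1101; Found 258.1074.

— is internally redundant: the molecular formula and the measured ion
determine the calculated m/z, and the found m/z must agree with it to
within a few ppm. `massaudit` extracts these quadruplets (formula, ion,
Calcd, Found) from SI-style text, recalculates the ion mass from first
principles, and classifies every internal inconsistency with a one-line
explanation and, where possible, a concrete correction. It is written for
authors checking their own SI before submission, and for reviewers and
editors screening many files at once.

## What it computes

The reference m/z for an ion `[nM + A − B]^z` is the electron-corrected
monoisotopic value

```
m/z = (n·M + m(A) − m(B) − z·m_e) / |z|,     m_e = 0.000548579909 Da
```

with deviations reported as `ppm = (found − calcd) / calcd × 10⁶`.
Mismatches are diagnosed into a fixed taxonomy, most specific hypothesis
first:

| category | what happened |
|---|---|
| `CONSISTENT` | calcd correct, found within the ppm threshold (default 10 ppm) |
| `THRESHOLD_EXCEEDED` | calcd correct, found beyond the threshold |
| `ELECTRON_MASS` | calcd computed for the neutral species (off by z·m_e) |
| `ADDUCT_OMITTED` | adduct atoms (`+H`, `+Na`, …) missing from the printed formula |
| `NOMINAL_MASS_ADDUCT` | adduct added at integer mass (23.0000 for Na, not 22.9898) |
| `MOLECULAR_WEIGHT` | average mass used instead of monoisotopic mass |
| `TRANSPOSED_DIGITS` / `SUBSTITUTED_DIGIT` | a unique single typing slip explains the number |
| `FORMULA_EDIT` | a small formula error (±H, ±Na, ±O, ±C, ±CH2, ±F, ±Cl, ±2H, ±2O) |
| `MALFORMED` / `UNEXPLAINED` | unparseable/incomplete record; no hypothesis fits |

See `docs/methods.md` for the full decision procedure and its numerical
choices.

## Worked example

No real SI files are shipped; the built-in generator writes a labeled
synthetic corpus so the whole pipeline can be exercised immediately:

```
$ massaudit generate --out demo --n-records 8 --seed 3
wrote 1 documents / 8 records to demo (ledger.csv holds the injected ground truth)

$ massaudit scan demo
demo/si_0001.txt:1 | C22H23N3NaO4 | [M+Na]+ | 416.1586 (416.1581) | 416.1585 | -0.24 ppm (+1.02 ppm) | ELECTRON_MASS: calcd was computed for the neutral species; the measured ion differs by 1 electron mass (-0.000549 Da)
demo/si_0001.txt:1 | C23H28FN4O2 | [M+H]+ | 411.2191 (411.2191) | 411.2205 | +3.40 ppm (+3.45 ppm) | CONSISTENT: calcd matches recalculated ion mass; found within threshold
demo/si_0001.txt:1 | C6H10N3O3 | [M + H]+ | 172.0717 (172.0717) | 172.0678 | -22.66 ppm *** (-22.48 ppm ***) | THRESHOLD_EXCEEDED: calcd is correct but found deviates -22.66 ppm (threshold 10 ppm)
demo/si_0001.txt:2 | C18H24O2 | [M + Na]+ | 295.3724 (295.1669) | 295.3724 | +0.00 ppm (+696.38 ppm ***) | MOLECULAR_WEIGHT: calcd matches the molecular weight (295.37); the monoisotopic ion mass is 295.1669
...
1 files scanned; 1 with AMM data (100%); 0 without AMM errors (0% of files with data); 8 AMMs, 5 with errors (4 excluding electron-mass errors).
```

Reading a line: printed calcd is followed by the recalculated value in
parentheses, then the found mass and the found-vs-calcd (found-vs-recalc)
ppm deviations; `***` flags a deviation beyond the threshold. Note the
molecular-weight record: calcd and found *agree perfectly* with each other
(+0.00 ppm) yet both are wrong by almost 700 ppm against the recalculated
monoisotopic mass — consistency of the measurement with a miscalculation is
exactly the trap the recalculation catches.

`massaudit scan FOLDER --out report.csv --summary summary.json` writes a
per-record CSV (or `--format json`; both carry identical content) and a
corpus summary with per-category tallies, files with/without AMM errors and
integer percentages. `--threshold-ppm` and `--tolerance-da` override the
defaults; exit status is 0 even when errors are found — findings are data,
not failures.

The same functionality is available as a library:

```python
from massaudit import find_amm_records, classify, SourceLocation

text = "HRMS (ESI/Q-TOF) m/z: [M + Na]+ Calcd for C13H17NO3Na 258.1101; Found 258.1074."
[rec] = find_amm_records(text, SourceLocation("si.txt", 1))
d = classify(rec)
print(d.category.value, round(d.recalculated_mass, 4), round(d.ppm_calcd_vs_found, 2))
# THRESHOLD_EXCEEDED 258.1101 -10.46
```

PDF input is supported through an optional, pluggable backend (`pypdf`);
plain-text documents (one page per form feed) work everywhere, and
unreadable files are skipped with a warning rather than aborting a scan.

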