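# fuzzyfmea

Fuzzy-FMEA microbial risk assessment for membrane-based water-for-injection
(WFI) systems.

Membrane-based WFI plants (RO / CEDI / UF trains with ambient storage and
distribution) lack the continuous thermal lethality of distillation, so
microbial proliferation — biofilm on membranes, vent-filter breakthrough,
seal leaks — is their dominant quality risk. Failure Mode and Effects
Analysis (FMEA) scores each failure mode for occurrence *O*, severity *S*
and detection *D* on 1–10 scales and prioritises by the risk priority
number

    RPN = O × S × D.

The product score has well-known pathologies: only 120 of the 1000 integer
(O, S, D) combinations yield distinct values (120 alone arises from 24
different triples), so failure modes with very different risk profiles
collide on the same RPN. This package implements the fuzzy alternative: a
Mamdani fuzzy inference system maps the mean expert scores through 125
linguistic IF–THEN rules (five terms per input, ten output terms,
triangular/trapezoidal membership functions, min implication, max
aggregation, centroid defuzzification) to a fuzzy RPN (fRPN) that breaks
those ties whenever the underlying (O, S, D) profiles differ.

The package ships:

- `fuzzyfmea.membership` / `fuzzyfmea.engine` — membership-function algebra
  and a pure, deterministic Mamdani kernel;
- `fuzzyfmea.rulebase` — construction, validation and CSV round-trip of the
  125-rule base;
- `fuzzyfmea.fmea` — worksheets, multi-expert rating panels, traditional
  RPN, dense ranking, tie diagnostics, and the RPN-lattice enumeration;
- `fuzzyfmea.case_study` — a fully transcribed 24-failure-mode WFI case
  study (three-expert panel) with reference scores for regression;
- `fuzzyfmea.synthetic` — seeded generators of synthetic expert panels
  (uniform, truncated-normal, and band-biased rating models);
- a `fuzzy-fmea` command-line tool (`assess`, `case-study`, `rules`,
  `simulate`).

## Worked example

Score the packaged case study, ranked by traditional RPN:

```
$ fuzzy-fmea case-study --sort rpn
code          rpn  rank     frpn  rank
--------------------------------------
FM9        213.33     1     6.58     1
FM14       182.00     2     6.58     1
FM12       130.67     3     5.82     3
FM13       130.67     3     5.82     3
FM15       121.33     4     5.79     5
FM11       116.67     5     5.74     6
FM16       116.67     5     5.81     4
...

Traditional-RPN ties:
  FM12, FM13 at RPN 130.67 -> fRPN [5.82, 5.82] (still tied)
  FM11, FM16 at RPN 116.67 -> fRPN [5.74, 5.81] (separated)
  FM23, FM24 at RPN 65.19 -> fRPN [5.27, 5.27] (still tied)
```

FM9 (RO membrane scaling/fouling) tops the traditional ranking and FM14
(UF fouling in the distribution loop) is second. The two CEDI/heat-exchanger
leak modes FM11 and FM16 receive the *same* traditional RPN (116.67) from
different mean profiles — (3.33, 7.00, 5.00) vs (3.00, 8.33, 4.67) — and the
fuzzy score separates them (5.74 vs 5.81), while FM12/FM13 and FM23/FM24,
whose expert ratings are literally identical, remain tied under both scores,
exactly as they should.

The same pipeline runs on your own data:

```sh
fuzzy-fmea assess --ratings my_ratings.csv --out scores.csv
fuzzy-fmea rules export --out rules.csv       # inspect/edit the 125 rules
fuzzy-fmea assess --ratings my_ratings.csv --rulebase rules.csv
fuzzy-fmea simulate --n-fm 24 --experts 3 --seed 7 --assess
```

Ratings CSV is long-form with columns `expert,code,O,S,D` (integers 1–10).

From Python:

```python
from fuzzyfmea import FuzzySystem, run_case_study

table = run_case_study()                 # 24-row risk-score table
fis = FuzzySystem.default()
fis.infer(4.33, 9.0, 4.67)               # -> 6.58 (fRPN for FM14's means)
```

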