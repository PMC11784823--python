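# Methods

## Model

Each failure mode in a membrane-based WFI system is rated by a panel of
experts for occurrence (O), severity (S) and detection (D) on integer 1–10
scales. Detection is risk-directed: 1 means detection is *certain* (lowest
risk) and 10 means detectability is *very low* (highest risk). The panel is
aggregated by the unweighted arithmetic mean per failure mode; missing
scores are an error, never imputed.

Two scores are computed from the mean triple (Ō, S̄, D̄):

- **Traditional RPN** — the product Ō·S̄·D̄, in [1, 1000].
- **Fuzzy RPN (fRPN)** — a Mamdani fuzzy inference system maps
  (Ō, S̄, D̄) to a crisp score in [1, 10]:
  1. *Fuzzification*: each input is a singleton; its membership degree in
     each of five linguistic terms is read off the term's membership
     function.
  2. *Rule evaluation*: each of the 125 rules "IF o is Oᵢ AND s is Sᵢ AND
     d is Dᵢ THEN RPN is Rᵢ" gets activation weight
     α = min(µ_O, µ_S, µ_D), and its output term is clipped at α
     (min implication).
  3. *Aggregation*: the clipped output sets are combined by the pointwise
     maximum.
  4. *Defuzzification*: the centroid of the aggregated set, evaluated on a
     uniform grid over the output universe.

Both scores are reported rounded half-up to two decimals and ranked densely
descending (ties share a rank; the next distinct value takes the next
integer). Ranking operates on the *rounded* values: this is what makes
panels with slightly different raw products share a printed rank, and it is
the behaviour the packaged reference table exhibits.

## Linguistic variables and default breakpoints

All four universes are [1, 10] — the rating scales have no 0 score. The
five input terms sit on the linguistic bands of the scales
(level 1 = {1}, 2 = {2, 3}, 3 = {4, 5, 6}, 4 = {7, 8}, 5 = {9, 10}):

- **Severity, detection** — five triangular terms with peaks at
  1, 2.5, 5, 7.5, 10; each term's feet lie at the neighbouring peaks, and
  the first/last terms are shouldered at the universe bounds (degenerate
  foot = peak, membership 1 at the shared breakpoint).
- **Occurrence** — five trapezoidal terms with plateaus [1,1], [2,3],
  [4,6], [7,8], [9,10] and limbs reaching the adjacent plateau edges, so
  each band core has full membership and adjacent terms half-overlap.
- **Output (fRPN)** — ten triangular terms ("none" … "very high") peaked at
  the integer scores 1…10 with feet at ±1, shouldered at the bounds.

Every default variable satisfies two structural invariants that the
constructor enforces for *any* configuration: term prototypes strictly
increase along the risk order, and the union of supports covers the
universe (so at least one rule always fires). Crisp inputs outside a
universe raise an error rather than being clipped.

These breakpoints are this package's own defaults, chosen to anchor the
published band structure of the rating scales; they are fully configurable
through the JSON/YAML system config (`save_fis_config` / `load_fis_config`,
round-trip stable).

## Rule base

Rules are indexed lexicographically with occurrence slowest-varying:
index = (o−1)·25 + (s−1)·5 + d, a bijection {1..5}³ → {1..125}. The default
consequent for antecedent levels (o, s, d) is the linear rescale of
o+s+d from [3, 15] onto [1, 10], rounded half-up, with one pinned override:
(2, 5, 5) → level 9. This is the simplest monotone mapping consistent with
the two anchor rules the case study documents — rule 16 (remote occurrence,
high severity, certain detection → "Low", level 3) and rule 50 (low, very
high, very low → "High", level 9) — and is non-decreasing in each
antecedent level (verified exhaustively). The full 125-rule table of the
original study is not published; the default base is a stated
reconstruction, and any complete base can be supplied as CSV
(numeric levels or canonical labels; "remote" and "almost none" are
synonyms for level 1).

## Numerical choices

- **Centroid grid**: uniform, step 0.01 over [1, 10] (901 points). The end
  points carry half weight (trapezoidal quadrature); a plain sum biases the
  centroid by O(step) whenever the aggregated set touches a universe
  boundary, and with the half-weights the result moves by < 10⁻³ when the
  step is halved (tested on 100 random inputs). Grid error is far below the
  2-decimal reporting precision.
- **Engine evaluation**: rules sharing a consequent are collapsed before
  gridding (max of their α per output level), which is algebraically
  identical to per-rule min/max aggregation; the test suite checks exact
  agreement with the literal per-rule route.
- **Rounding**: decimal round-half-up (0.005 → 0.01), applied only at
  reporting; all internal arithmetic is unrounded.
- **Degenerate membership functions** (foot coinciding with peak/shoulder)
  evaluate to 1 at the shared breakpoint, keeping boundary terms
  well-defined.
- Inference is pure — no random state anywhere in the engine.

## Case-study fixtures

The packaged case study transcribes a 24-failure-mode FMEA worksheet for a
membrane-based WFI plant (pretreatment, production, storage/distribution
and auxiliary subsystems) and a three-expert rating panel. Loading
integrity-checks the fixtures: FM1…FM24 present in both files, exactly
three experts, and every reference RPN within 0.005 of the recomputed
product of mean scores. The reference table's two traditional-rank entries
that contradict its own RPN column (FM22 and FM6, printed one rank too
high) are known errata of the source material; tests pin the other 22
rows. The reference fRPN column is metadata only: it was produced with
membership-function breakpoints and rule consequents that are not fully
published, so no test (and no default configuration) targets it.

## Synthetic panels

`generate_panel` emulates the case-study structure (K experts × N failure
modes × three integer scores) with a single seeded RNG stream:

- `uniform` — scores i.i.d. uniform on {1..10}; useful for lattice/collision
  arguments (a single-expert panel admits only 120 distinct products, so
  ≥121 modes force a tie by pigeonhole).
- `truncnorm` — per-dimension normal truncated to [0.5, 10.5] and rounded;
  defaults (O 3.5±2, S 7±2, D 3.5±2) imitate the case-study marginals,
  where severity runs high and occurrence/detection sit low-to-mid.
- `band` (default) — a latent 5-level linguistic band per (mode, dimension),
  shared by all experts, who then rate uniformly within the band. This
  mirrors panels that agree linguistically but differ on the exact score.

`tie_injection` copies one mode's ratings onto another, forcing exact
traditional-RPN ties on demand. What the generator does *not* model:
inter-expert bias or correlation structure, expert calibration/weighting,
and any dependence between failure modes — so passing tests demonstrate
pipeline correctness and determinism on panel-shaped data, not fidelity to
any particular expert population.

`clustering_experiment` runs seeded replicate panels end-to-end and reports
the fraction of failure-mode pairs tied under the rounded RPN vs the
rounded fRPN. Note that at 2-decimal rounding the fRPN lives on a much
shorter scale ([1, 10] vs [1, 1000]), so its raw tie fraction is not
automatically smaller; the fuzzy score's value is that it separates ties
whose underlying profiles differ (e.g. FM11/FM16 in the case study) while
leaving genuinely identical profiles tied.

## Problem sizes used by tests and the acceptance script

The suite exercises all 125 prototype points against an independent
quadrature oracle, 100 random inputs for grid-refinement stability, 1000
random inputs for output bounds, and 100 seeded synthetic panels of the
case study's size (24 modes × 3 experts) end-to-end. The acceptance script
runs the full case study, the exhaustive 1000-triple lattice enumeration,
and a 20-panel clustering experiment.

## Known limitations

- The default rule base and membership breakpoints are principled
  reconstructions, not the original study's (unpublished) configuration;
  fRPN values therefore match that study's printed fRPN column only in
  behaviour (bounds, monotonicity, tie separation), not numerically.
- Equal weighting of O, S and D within each rule's min-activation is
  inherited from the method; no severity weighting or FMECA-style
  criticality is provided.
- Failure modes are scored independently; interactions between failure
  modes are out of scope.
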