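# Methods

## The model

`edplot` operates on a two-level summary of a systematic review. At the
bottom level each *outcome* in each study is reduced to a ternary effect
direction: POSITIVE (the health outcome improved), NEGATIVE (deteriorated)
or NO_CHANGE. POSITIVE always denotes *improvement in health* regardless of
the measurement's polarity; harmonizing polarity (a lower symptom score
counts as improvement) is the data preparer's responsibility and is assumed
done before input. Magnitudes, confidence intervals and p-values of the
primary studies are deliberately not modeled — direction is the common
metric precisely because nothing richer is comparable across the studies.

### Within-study synthesis (the 70% rule)

Outcomes are grouped into conceptually similar *outcome domains* within
each study. A domain reports POSITIVE (or NEGATIVE) when at least 70% of
its outcomes agree on that direction; otherwise it reports UNCLEAR — no
clear effect / mixed effects / conflicting findings, drawn as the sideways
arrow ◂▸. Two numerical commitments matter here:

- **Inclusivity.** The threshold is `≥ 7/10`, evaluated with
  `fractions.Fraction`, never floats: 7 positive outcomes of 10 is a clear
  majority and must qualify deterministically, which a float comparison at
  exactly 0.70 cannot guarantee.
- **Denominator.** By default the denominator is *all* outcomes in the
  domain, so NO_CHANGE outcomes dilute both directions (2 positive + 1
  no-change → 2/3 < 7/10 → UNCLEAR). This is the conservative reading of
  "70% of outcomes". `denominator="directional"` restricts the denominator
  to outcomes that moved; it is exposed on `synthesize_domain`,
  `synthesize_all` and as `--denominator` on the CLI because review teams
  disagree on this point and the choice should be visible, not buried.

A domain whose outcomes are unanimously NO_CHANGE also returns UNCLEAR: the
sideways arrow's meaning covers both "no change" and "conflicting", and the
per-label counts are kept on the result so a renderer (or reader) can tell
the two apart. Raw outcomes can never be UNCLEAR; that label exists only at
the domain level.

### Cross-study sign test

For one domain, each study contributes one vote by its domain-level arrow.
UNCLEAR studies cannot be said to represent either direction and are
excluded from the test — but never from the accounting: the result object
records how many were excluded out of how many, because a test computed on
a minority of the review can misrepresent the synthesis (e.g. 20 studies of
which 11 are unclear leaves a 9-study test).

With `a` positive and `b` negative votes, `n = a + b` and
`k = max(a, b)`, the two-tailed p-value under the fair-coin null is the
doubled upper tail capped at one, `min(1, 2·Σ_{i=k}^n C(n,i)/2^n)`,
computed in exact integer/rational arithmetic and converted to float only
at the end. Under the symmetric null, doubling coincides with summing both
tails (the test suite verifies this equivalence exhaustively for
`n ≤ 25`), and it matches the convention of common exact-binomial
calculators. Display formatting rounds to four decimals without a leading
zero (".0039"); the full-precision value is retained on the result.

Caveat flags, not verdicts:

- `NO_ELIGIBLE_STUDIES` — every study unclear; p undefined (`None`).
- `HIGH_EXCLUSION_FRACTION` — more than 1/2 of the studies were excluded.
- `SMALL_K` — fewer than 6 eligible studies. Six is the smallest review in
  which even a unanimous split can reach p < 0.05 (2·(1/2)^6 = 0.03125;
  at five studies the floor is 0.0625), so below it the test is
  uninformative at the conventional threshold.
- `PUBLICATION_BIAS_UNASSESSED` — always set unless the caller asserts
  bias was assessed; the test is inappropriate when publication bias is
  suspected.

The 1/2 and 6 cutoffs are this package's declared heuristics (both are
keyword-configurable on `run_sign_test`); the first mirrors the
11-of-20-excluded scenario above, the second is the exact attainability
bound just derived. Result objects expose no "significant: yes/no" field,
and the formatted output appends a fixed caution against describing
direction patterns as statistically significant or not.

## Power diagnostics

`edplot.power` quantifies how weak the sign test is in realistic reviews.
A scenario draws `k_studies` i.i.d. studies: unclear with probability
`p_unclear`, otherwise positive with probability `p_positive`. Each
replicate review is scored by the same `exact_sign_test` used in the
pipeline, rejecting when the p-value is defined and ≤ `alpha` (default
0.05, the test's discreteness makes true size well below that — at k = 10
under the null the exact rejection rate is 2·P(Bin(10,½) ≥ 9) ≈ 0.0215).
Reported: rejection rate with its binomial Monte-Carlo standard error, mean
eligible studies, and the fraction of replicates where the test was
undefined. `exact_rejection_rate` computes the same quantity by trinomial
enumeration and serves as the analytic cross-check in the tests.

Defaults: 10 000 replicates (standard error ≤ 0.005 on any rate), seeded
`numpy.random.default_rng` (PCG64) — one integer seed fully determines all
replicates. The i.i.d. assumption is the minimal model exposing the
counting-power problem; between-study dependence, which also undermines the
binomial null itself, is a known limitation this module does not model.

## The plot

Layout (`layout_plot`) is separated from drawing (`render_svg`,
`render_png`). The grid has one row per study and one column per domain;
every (study, domain) pair gets exactly one cell, and pairs without data
render an explicit empty cell so no study silently disappears — the plot's
ability to represent *all* studies (including those the sign test drops) is
its main strength over the bare test.

- **Glyphs:** ▲ positive, ▼ negative, ◂▸ unclear (kept as the
  two-character sequence for fidelity to the template, not a single ↔).
- **Arrow size:** small/medium/large for intervention-group final sample
  size < 50 / 50–300 / > 300, rendered at 10/14/19 pt (configurable).
  Boundary inclusivity: 300 is medium, 301 large; 49 small, 50 medium. A
  missing sample size renders medium with an explicit "n unknown"
  annotation rather than dropping or down-weighting the study.
- **Subscript:** the number of outcomes an arrow summarizes, shown when
  greater than one.
- **Row shading:** green `#2E7D32` (high quality / low risk of bias),
  amber `#F9A825` (moderate / some concerns), red `#C62828` (low / high
  risk), at 25% fill opacity behind black text for contrast. The quality
  scale is fixed at exactly three levels to match the three colors; other
  appraisal scales must be mapped before input. A colorblind-safe option
  swaps in Okabe–Ito hues plus per-quality pattern fills so quality never
  depends on color discrimination alone.
- **Determinism:** the SVG is assembled with fixed element order and number
  formatting; an identical spec yields byte-identical output (tested). The
  legend is always emitted and versioned (`data-renderer` attribute) so
  plots are self-describing. An optional footer row per domain shows vote
  counts and the display-rounded p-value; it is off by default since the
  canonical plot carries no test results.

PNG export redraws the same layout with matplotlib at a configurable DPI
rather than rasterizing the SVG; the two backends share the spec, not the
drawing code.

## Input, output, fixtures

Input is long format — one row per outcome with study characteristics
repeated — because it is unambiguous about within-study multiplicity; a
wide per-study table must be melted first. Direction and quality tokens map
through an explicit, case-insensitive, whitespace-stripping vocabulary
(default: positive/+/up/improved; negative/-/down/worsened; none/0/no
change/null), and unmapped tokens are hard errors listing every offending
row at once. CSV, TSV and JSON round-trip losslessly on canonical form
(sorted rows); JSON results files reparse to equal in-memory objects.

`generate_fixture` produces reproducible synthetic review tables
(per-outcome direction probabilities defaulting to 0.6/0.2/0.2
positive/negative/no-change, quality mix 0.3/0.5/0.2 high/moderate/low,
intervention-group n uniform on 20–500, 1–4 outcomes per domain) — chosen
as a plausible mixed-quality public-health review; its output always passes
validation. The packaged `housing_example` preset is a **synthetic**
stand-in for a real housing-improvement review: the published account of
that review prints only the domain-level vote counts (9 positive/1 unclear
of 10; 5/1/1 of 7; 5/1/4 of 10), so the preset invents minimal per-study
outcome lists that synthesize to exactly those counts under the 70% rule —
including one 7-positive/3-negative study that pins the threshold's
inclusive boundary and one unknown-n study exercising the annotation path.
What passing the preset shows is that the pipeline reproduces the published
vote counts and p-values from outcome-level input; it says nothing about
the substantive housing data, which the preset does not contain.

## What the synthetic data does not capture

Simulated and preset reviews have independent studies, error-free direction
extraction, and clean three-level quality ratings. Real reviews have
correlated studies (shared populations, instruments, investigators —
violating the binomial null), extraction ambiguity in what counts as
"improvement", and appraisal scales that map awkwardly onto three levels.
Green tests therefore demonstrate computational correctness of the rules,
not robustness of the sign test's assumptions in the field.

## Known limitations

- No adjustment for multiplicity across outcome domains; each domain is
  tested separately.
- No model of between-study dependence, in the simulation or the test.
- Quality must be pre-mapped to three levels; the package will not guess.
- Rendering targets modest review sizes; very large reviews are not
  auto-paginated.
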