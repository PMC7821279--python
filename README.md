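# edplot

Effect direction plots and exact sign tests for **synthesis without
meta-analysis** in systematic reviews.

Many reviews — especially of public-health and complex interventions —
cannot pool effect sizes: outcomes are measured in incompatible ways across
studies. *Effect direction* (did the outcome improve, deteriorate, or show
no change?) is a standardized metric that works anyway. `edplot` implements
the revised effect direction plot method built on it, for review teams who
need a transparent, significance-free link between study data and synthesis
conclusions:

1. **Within-study synthesis.** Related outcomes in a study are grouped into
   outcome domains (e.g. cough frequency + wheeze → *respiratory health*).
   A domain reports direction *d* when at least 70% of its outcomes agree:
   with `n_d / n ≥ 7/10` (compared in exact rational arithmetic, so 7 of 10
   qualifies deterministically), the domain's arrow is ▲ (positive health
   impact) or ▼ (negative); otherwise ◂▸ — no clear effect / conflicting
   findings. Statistical significance of the primary results plays no role.
2. **Cross-study sign test.** For each domain, studies vote by their
   domain-level arrow; unclear (◂▸) studies are excluded from the count.
   With `a` positive and `b` negative votes, `n = a + b`,
   `k = max(a, b)`, the exact two-tailed p-value under the fair-coin null
   `H0: Pr(positive) = 1/2` is

   ```
   p = min(1, 2 · Σ_{i=k}^{n} C(n, i) · (1/2)^n)
   ```

   computed in exact integer arithmetic. Results carry explicit caveat
   flags (many excluded studies, too few studies for the test ever to reach
   p < 0.05, publication bias not assessed) instead of a significant-yes/no
   verdict.
3. **The plot.** A deterministic SVG (or PNG) grid: one row per study,
   shaded green/yellow/red by quality rating; one column per domain; arrows
   sized small/medium/large by the intervention-group final sample size
   (< 50 / 50–300 / > 300) with a subscript giving the number of outcomes
   each arrow summarizes.
4. **Power diagnostics.** Monte-Carlo (plus exact-enumeration) estimates of
   the sign test's rejection rate as a function of review size, the true
   positive-direction probability and the fraction of unclear studies —
   quantifying how underpowered the test is in small reviews.

## Worked example

The packaged synthetic review (`edplot.io.housing_example`) mirrors a
10-study review of warmth and energy-efficiency housing improvements across
three outcome domains:

```python
from edplot import describe, run_sign_tests, synthesize_all
from edplot.io import housing_example

records, studies = housing_example()
syntheses = synthesize_all(records, studies)
for result in run_sign_tests(syntheses):
    print(result.domain_id, result.n_positive_studies,
          result.n_negative_studies, result.n_excluded_unclear,
          f"p={result.p_value:.6f}")
```

prints

```
general_health 5 1 1 p=0.218750
housing_condition 9 0 1 p=0.003906
respiratory_health 5 1 4 p=0.218750
```

Housing condition improved in 9 of 10 studies (one study's outcomes
conflicted and is excluded): a 9–0 split has two-tailed p = .0039 under the
fair-coin null. General health and respiratory health both split 5–1 among
the studies with a clear direction, giving p = .2188 — the same test despite
respiratory health excluding four studies rather than one, which is exactly
why the result objects carry exclusion counts and caveat flags.

The same pipeline is available from a shell:

```sh
edplot fixture -o review.csv --preset housing_example
edplot synthesize review.csv -o results.json
edplot plot review.csv -o review.svg
edplot power -k 5 -k 6 -k 10 --p-positive 1.0 --seed 1
```

and `examples/` contains one short narrative script per capability.

## Layout

- `src/edplot/model.py` — domain types and dataset validation
- `src/edplot/synthesis.py` — 70% majority rule, arrow size classes
- `src/edplot/signtest.py` — exact two-tailed sign test and caveats
- `src/edplot/power.py` — Monte-Carlo / exact power diagnostics
- `src/edplot/layout.py`, `render.py` — plot grid, SVG/PNG rendering
- `src/edplot/io.py` — CSV/TSV/JSON input, results output, fixtures
- `src/edplot/cli.py` — `edplot` command (validate / synthesize / plot /
  power / fixture)

See `docs/methods.md` for the model, its assumptions and design choices.
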