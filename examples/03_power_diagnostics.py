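"""How much power does the sign test actually have in a small review?

Simulates reviews of k studies where each non-conflicting study is positive
with probability 0.8, and a varying share of studies synthesize to
unclear/conflicting (and are excluded from the test).
"""

from edplot import PowerScenario, estimate_power, exact_rejection_rate

print(f"{'k':>3} {'p_unclear':>9} {'power(MC)':>10} {'power(exact)':>12} "
      f"{'mean eligible':>13}")
for k in (5, 6, 10, 20):
    for p_unclear in (0.0, 0.3):
        sc = PowerScenario(k_studies=k, p_positive=0.8, p_unclear=p_unclear,
                           replicates=10_000, seed=42)
        est = estimate_power(sc)
        exact = exact_rejection_rate(k, 0.8, p_unclear)
        print(f"{k:>3} {p_unclear:>9.1f} {est.rejection_rate:>10.4f} "
              f"{exact:>12.4f} {est.mean_eligible:>13.2f}")

# Power is zero below 6 eligible studies even when every study is positive
# (a unanimous 5/5 split gives p = 0.0625 > 0.05), and excluding unclear
# studies erodes power further — the test is weakest exactly where vote
# counting tends to be used.
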