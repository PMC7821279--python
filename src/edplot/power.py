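"""Monte-Carlo power diagnostics for the cross-study sign test.

The sign test is typically underpowered exactly where vote counting is
needed: reviews with few studies, further thinned by excluding studies with
unclear direction.  This module quantifies that caveat.  A review of
``k_studies`` is simulated with each study independently unclear with
probability ``p_unclear`` and otherwise positive with probability
``p_positive`` (else negative); the sign test is run on each simulated
review and the rejection rate at ``alpha`` estimated.

Studies are modeled i.i.d. — the minimal model that exposes the counting
power problem; between-study dependence (which the binomial null does not
accommodate) is a documented limitation, not modeled.

Randomness contract: all replicates are drawn from ``numpy``'s PCG64
generator seeded with the scenario's single integer seed, so a seed fully
determines the output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from fractions import Fraction
from math import comb, sqrt
from typing import Iterable, Sequence

import numpy as np

from .signtest import exact_sign_test


@dataclass(frozen=True)
class PowerScenario:
    """One simulated-review configuration.

    k_studies     number of studies in the review
    p_positive    P(positive | study has a clear direction)
    p_unclear     P(study synthesizes to unclear and is excluded)
    alpha         rejection threshold applied to the two-tailed p
    replicates    Monte-Carlo sample size
    seed          integer seed; fully determines the replicates
    """

    k_studies: int
    p_positive: float
    p_unclear: float = 0.0
    alpha: float = 0.05
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must be in [0, 1]")
        if not 0.0 <= self.p_unclear < 1.0:
            raise ValueError("p_unclear must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo estimates for one scenario."""

    rejection_rate: float
    mean_eligible: float
    undefined_rate: float
    mc_se: float  # binomial standard error of rejection_rate


def simulate_reviews(scenario: PowerScenario) -> np.ndarray:
    """Draw replicate reviews; returns an (replicates, 3) array of
    (n_positive, n_negative, n_unclear) study counts per replicate."""
    rng = np.random.default_rng(scenario.seed)
    k = scenario.k_studies
    u = rng.random((scenario.replicates, k))
    unclear = u < scenario.p_unclear
    # conditional on clear, an independent uniform decides the direction
    v = rng.random((scenario.replicates, k))
    positive = ~unclear & (v < scenario.p_positive)
    negative = ~unclear & ~positive
    return np.stack(
        [positive.sum(axis=1), negative.sum(axis=1), unclear.sum(axis=1)],
        axis=1,
    )


def _pvalue_table(k: int) -> dict[tuple[int, int], float]:
    """p-value for every (n_pos, n_eligible) with 1 <= n_eligible <= k."""
    table: dict[tuple[int, int], float] = {}
    for n in range(1, k + 1):
        for a in range(n + 1):
            table[(a, n)] = exact_sign_test(a, n - a)
    return table


def estimate_power(scenario: PowerScenario) -> PowerEstimate:
    """Estimate the sign test's rejection rate for a scenario.

    rejection_rate counts replicates with a *defined* p <= alpha; replicates
    in which every study is unclear contribute to undefined_rate instead
    (the test cannot be run at all there).
    """
    counts = simulate_reviews(scenario)
    table = _pvalue_table(scenario.k_studies)
    n_rej = 0
    n_undef = 0
    eligible_total = 0
    for n_pos, n_neg, _ in counts:
        n_elig = int(n_pos + n_neg)
        eligible_total += n_elig
        if n_elig == 0:
            n_undef += 1
        elif table[(int(n_pos), n_elig)] <= scenario.alpha:
            n_rej += 1
    r = scenario.replicates
    rate = n_rej / r
    return PowerEstimate(
        rejection_rate=rate,
        mean_eligible=eligible_total / r,
        undefined_rate=n_undef / r,
        mc_se=sqrt(rate * (1.0 - rate) / r),
    )


def exact_rejection_rate(
    k: int,
    p_positive: float,
    p_unclear: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Exact rejection probability by enumerating the trinomial outcome space.

    Serves as the analytic reference for the Monte-Carlo estimate: sums
    P(n_unclear, n_pos) over all outcomes whose sign test p is defined and
    <= alpha.  Exact-rational binomial weights are mixed with float
    direction probabilities, so accuracy is limited only by float products.
    """
    pu = p_unclear
    pp = p_positive
    total = 0.0
    for n_unc in range(k + 1):
        w_unc = comb(k, n_unc) * (pu**n_unc) * ((1.0 - pu) ** (k - n_unc))
        n_elig = k - n_unc
        if n_elig == 0:
            continue
        for n_pos in range(n_elig + 1):
            if exact_sign_test(n_pos, n_elig - n_pos) <= alpha:
                w_dir = comb(n_elig, n_pos) * (pp**n_pos) * (
                    (1.0 - pp) ** (n_elig - n_pos)
                )
                total += w_unc * w_dir
    return total


def export_power_table(
    rows: Iterable[tuple[PowerScenario, PowerEstimate]],
    path,
) -> None:
    """Write scenario parameters and estimates to CSV, one row per scenario."""
    rows = list(rows)
    fields = [
        "k_studies", "p_positive", "p_unclear", "alpha", "replicates", "seed",
        "rejection_rate", "mean_eligible", "undefined_rate", "mc_se",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for scenario, estimate in rows:
            writer.writerow({**asdict(scenario), **asdict(estimate)})
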