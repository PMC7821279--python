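"""Cross-study exact sign test on domain-level effect directions.

After within-study synthesis, each study contributes one arrow per outcome
domain.  The sign test asks whether the split of positive vs negative
arrows could plausibly arise if either direction were equally likely
(binomial null with probability 1/2).  Studies whose domain-level result is
UNCLEAR cannot be said to represent either direction and are excluded from
the count — an exclusion the result object accounts for explicitly, because
excluding many studies can misrepresent the synthesis.

The two-tailed p-value doubles the tail probability of the more extreme
count and caps at 1.  Under the symmetric null this coincides with summing
both tails, and it reproduces the values printed by common exact-binomial
calculators.  All arithmetic is exact (integers / Fractions) until the
final conversion to float.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Iterable, Optional

from .model import Caveat, Direction, DomainSynthesis, SignTestResult

#: Fewer eligible studies than this can never reject at alpha=0.05 even when
#: unanimous (2 * (1/2)^5 = 0.0625 > 0.05), so the test is flagged SMALL_K.
SMALL_K_CUTOFF = 6

#: Excluding more than this fraction of studies flags the result as likely
#: to misrepresent the synthesis.
HIGH_EXCLUSION_CUTOFF = Fraction(1, 2)


class NoEligibleStudiesError(ValueError):
    """Raised when neither a positive nor a negative vote exists."""


def exact_sign_test(n_positive: int, n_negative: int) -> float:
    """Exact two-tailed binomial sign test p-value under null prob 1/2.

    With n = n_positive + n_negative eligible studies and
    k = max(n_positive, n_negative), returns
    ``min(1, 2 * sum_{i=k}^{n} C(n, i) / 2^n)`` computed in exact integer
    arithmetic and converted to float at the end.

    >>> exact_sign_test(9, 0)
    0.00390625
    >>> exact_sign_test(5, 1)
    0.21875
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("vote counts must be >= 0")
    n = n_positive + n_negative
    if n == 0:
        raise NoEligibleStudiesError("no studies with a clear direction")
    k = max(n_positive, n_negative)
    tail = sum(comb(n, i) for i in range(k, n + 1))
    p = Fraction(2 * tail, 2**n)
    return float(min(p, Fraction(1)))


def format_p(p: Optional[float], digits: int = 4) -> str:
    """Display-round a p-value in the leading-zero-free house style.

    >>> format_p(0.00390625)
    '.0039'
    >>> format_p(1.0)
    '1.0000'
    """
    if p is None:
        return "NA"
    text = f"{p:.{digits}f}"
    return text[1:] if text.startswith("0.") else text


def count_directions(
    syntheses: Iterable[DomainSynthesis],
) -> tuple[int, int, int]:
    """Tally domain-level arrows into (positive, negative, excluded-unclear).

    All syntheses must belong to one domain with at most one per study;
    duplicates raise because a study may vote only once.
    """
    syntheses = list(syntheses)
    domains = {s.domain_id for s in syntheses}
    if len(domains) > 1:
        raise ValueError(f"syntheses span multiple domains: {sorted(domains)}")
    seen: set[str] = set()
    n_pos = n_neg = n_unc = 0
    for s in syntheses:
        if s.study_id in seen:
            raise ValueError(
                f"study {s.study_id!r} appears twice in domain "
                f"{s.domain_id!r}"
            )
        seen.add(s.study_id)
        if s.direction is Direction.POSITIVE:
            n_pos += 1
        elif s.direction is Direction.NEGATIVE:
            n_neg += 1
        else:
            n_unc += 1
    return n_pos, n_neg, n_unc


def run_sign_test(
    syntheses: Iterable[DomainSynthesis],
    total_study_count: Optional[int] = None,
    *,
    publication_bias_assessed: bool = False,
    small_k_cutoff: int = SMALL_K_CUTOFF,
    high_exclusion_cutoff: Fraction = HIGH_EXCLUSION_CUTOFF,
) -> SignTestResult:
    """Assemble counts, p-value and interpretation caveats for one domain.

    ``total_study_count``, when given, must equal the number of syntheses
    (positive + negative + excluded): studies with no data in the domain do
    not enter the test and are not "excluded" from it.  Caveats:

    * NO_ELIGIBLE_STUDIES — every study was unclear; p undefined.
    * HIGH_EXCLUSION_FRACTION — more than ``high_exclusion_cutoff`` of the
      studies were excluded as unclear.
    * SMALL_K — fewer than ``small_k_cutoff`` eligible studies; the test
      cannot reach p < 0.05 at the default cutoff even when unanimous.
    * PUBLICATION_BIAS_UNASSESSED — set unless the caller asserts bias was
      assessed; the test should not be used if publication bias is suspected.
    """
    syntheses = list(syntheses)
    domain_id = syntheses[0].domain_id if syntheses else ""
    n_pos, n_neg, n_unc = count_directions(syntheses)
    n_total = n_pos + n_neg + n_unc
    if total_study_count is not None and total_study_count != n_total:
        raise ValueError(
            f"total_study_count={total_study_count} does not match the "
            f"{n_total} syntheses supplied"
        )

    caveats: set[Caveat] = set()
    if not publication_bias_assessed:
        caveats.add(Caveat.PUBLICATION_BIAS_UNASSESSED)
    if n_pos + n_neg == 0:
        caveats.add(Caveat.NO_ELIGIBLE_STUDIES)
        p: Optional[float] = None
    else:
        p = exact_sign_test(n_pos, n_neg)
    if n_total and Fraction(n_unc, n_total) > high_exclusion_cutoff:
        caveats.add(Caveat.HIGH_EXCLUSION_FRACTION)
    if n_pos + n_neg < small_k_cutoff:
        caveats.add(Caveat.SMALL_K)

    return SignTestResult(
        domain_id=domain_id,
        n_positive_studies=n_pos,
        n_negative_studies=n_neg,
        n_excluded_unclear=n_unc,
        n_total_studies=n_total,
        p_value=p,
        caveats=frozenset(caveats),
    )


def run_sign_tests(
    syntheses: Iterable[DomainSynthesis],
    **kwargs,
) -> list[SignTestResult]:
    """Run the sign test for every domain present, sorted by domain_id."""
    by_domain: dict[str, list[DomainSynthesis]] = {}
    for s in syntheses:
        by_domain.setdefault(s.domain_id, []).append(s)
    return [run_sign_test(group, **kwargs) for _, group in sorted(by_domain.items())]


#: Fixed interpretation note rendered with every formatted result: patterns
#: of effect direction should not be described as statistically significant
#: or not; the p-value only gauges whether the split could be chance alone.
CAVEAT_NOTE = (
    "Interpret with caution: avoid stating that the pattern of effect "
    "direction is or is not 'statistically significant'. The sign test only "
    "indicates how readily the observed split of positive and negative "
    "directions could arise by chance, and excludes studies with unclear "
    "direction."
)


def describe(result: SignTestResult) -> str:
    """Human-readable one-domain summary including the fixed caveat note."""
    lines = [
        f"domain {result.domain_id!r}: "
        f"{result.n_positive_studies} positive, "
        f"{result.n_negative_studies} negative, "
        f"{result.n_excluded_unclear} unclear (excluded) "
        f"of {result.n_total_studies} studies",
        f"  two-tailed sign test p = {format_p(result.p_value)}",
    ]
    for c in sorted(result.caveats, key=lambda c: c.value):
        lines.append(f"  caveat: {c.value}")
    lines.append(f"  note: {CAVEAT_NOTE}")
    return "\n".join(lines)
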