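"""Exact two-tailed sign test and its caveat accounting."""

from fractions import Fraction
from math import comb

import pytest
from scipy.stats import binomtest

from edplot import (
    Caveat,
    Direction,
    count_directions,
    exact_sign_test,
    format_p,
    run_sign_test,
    run_sign_tests,
    synthesize_domain,
)
from edplot.signtest import NoEligibleStudiesError

P, N = Direction.POSITIVE, Direction.NEGATIVE


def brute_force_two_tail(a: int, b: int) -> float:
    """Sum binomial point masses over both tails at the observed extremity."""
    n = a + b
    k = max(a, b)
    mass = sum(comb(n, i) for i in range(k, n + 1))          # upper tail
    mass += sum(comb(n, i) for i in range(0, n - k + 1))     # lower tail
    if n - k >= k:  # tails overlap when the split is perfectly balanced
        mass = 2**n
    return float(min(Fraction(mass, 2**n), Fraction(1)))


def syn(study, direction, domain="dom"):
    labels = {
        Direction.POSITIVE: [P],
        Direction.NEGATIVE: [N],
        Direction.UNCLEAR: [P, N],
    }[direction]
    return synthesize_domain(labels, study_id=study, domain_id=domain)


class TestExactSignTest:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (9, 0, 0.00390625),   # 10-study review, one unclear excluded
            (5, 1, 0.21875),      # reported twice in the worked review
            (1, 1, 1.0),          # perfectly balanced, doubling capped at 1
            (8, 1, 0.0390625),    # 20-study hypothetical, 11 unclear excluded
        ],
    )
    def test_worked_values(self, a, b, expected):
        assert exact_sign_test(a, b) == expected

    def test_display_rounding(self):
        assert format_p(exact_sign_test(9, 0)) == ".0039"
        assert format_p(exact_sign_test(5, 1)) == ".2188"
        assert format_p(None) == "NA"
        assert format_p(1.0) == "1.0000"

    def test_agrees_with_brute_force_for_all_small_counts(self):
        for n in range(1, 26):
            for a in range(n + 1):
                assert exact_sign_test(a, n - a) == brute_force_two_tail(a, n - a)

    def test_agrees_with_scipy_binomtest(self):
        # independent library cross-check on a grid
        for n in range(1, 21):
            for a in range(n + 1):
                expected = binomtest(a, n, 0.5, alternative="two-sided").pvalue
                assert exact_sign_test(a, n - a) == pytest.approx(expected)

    def test_symmetry(self):
        for a in range(0, 12):
            for b in range(0, 12):
                if a + b == 0:
                    continue
                assert exact_sign_test(a, b) == exact_sign_test(b, a)

    def test_unanimous_closed_form(self):
        for n in range(1, 21):
            assert exact_sign_test(n, 0) == min(1.0, 2.0 * 0.5**n)

    def test_monotone_in_imbalance(self):
        for n in range(1, 20):
            ps = [exact_sign_test(a, n - a) for a in range((n + 1) // 2, n + 1)]
            assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_errors(self):
        with pytest.raises(NoEligibleStudiesError):
            exact_sign_test(0, 0)
        with pytest.raises(ValueError):
            exact_sign_test(-1, 2)


class TestCountDirections:
    def test_housing_condition_votes(self):
        syns = [syn(f"S{i}", Direction.POSITIVE) for i in range(9)]
        syns.append(syn("S9", Direction.UNCLEAR))
        assert count_directions(syns) == (9, 0, 1)

    def test_mixed_votes(self):
        syns = (
            [syn(f"S{i}", Direction.POSITIVE) for i in range(5)]
            + [syn("S5", Direction.NEGATIVE)]
            + [syn(f"S{i + 6}", Direction.UNCLEAR) for i in range(4)]
        )
        assert count_directions(syns) == (5, 1, 4)

    def test_empty_domain(self):
        assert count_directions([]) == (0, 0, 0)

    def test_duplicate_study_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            count_directions([syn("S1", P), syn("S1", N)])

    def test_multiple_domains_rejected(self):
        with pytest.raises(ValueError, match="domains"):
            count_directions([syn("S1", P, "a"), syn("S2", P, "b")])


class TestRunSignTest:
    def test_headline_domain(self):
        syns = [syn(f"S{i}", Direction.POSITIVE) for i in range(9)]
        syns.append(syn("S9", Direction.UNCLEAR))
        result = run_sign_test(syns, total_study_count=10)
        assert result.p_value == 0.00390625
        assert Caveat.HIGH_EXCLUSION_FRACTION not in result.caveats
        assert Caveat.SMALL_K not in result.caveats
        assert Caveat.PUBLICATION_BIAS_UNASSESSED in result.caveats

    def test_high_exclusion_hypothetical(self):
        # 20 studies: 8 positive, 1 negative, 11 unclear -> test covers
        # fewer than half the review and must say so
        syns = (
            [syn(f"S{i:02d}", Direction.POSITIVE) for i in range(8)]
            + [syn("S08", Direction.NEGATIVE)]
            + [syn(f"S{i + 9:02d}", Direction.UNCLEAR) for i in range(11)]
        )
        result = run_sign_test(syns, total_study_count=20)
        assert result.p_value == 0.0390625
        assert Caveat.HIGH_EXCLUSION_FRACTION in result.caveats

    def test_no_eligible_studies(self):
        syns = [syn(f"S{i}", Direction.UNCLEAR) for i in range(3)]
        result = run_sign_test(syns)
        assert result.p_value is None
        assert Caveat.NO_ELIGIBLE_STUDIES in result.caveats
        assert result.n_total_studies == 3

    def test_small_k_flag(self):
        syns = [syn(f"S{i}", Direction.POSITIVE) for i in range(5)]
        assert Caveat.SMALL_K in run_sign_test(syns).caveats
        syns.append(syn("S5", Direction.POSITIVE))
        assert Caveat.SMALL_K not in run_sign_test(syns).caveats

    def test_publication_bias_flag_clearable(self):
        result = run_sign_test([syn("S1", P)], publication_bias_assessed=True)
        assert Caveat.PUBLICATION_BIAS_UNASSESSED not in result.caveats

    def test_total_count_must_match_partition(self):
        with pytest.raises(ValueError, match="does not match"):
            run_sign_test([syn("S1", P)], total_study_count=5)

    def test_run_sign_tests_splits_by_domain(self):
        syns = [syn("S1", P, "a"), syn("S2", N, "a"), syn("S1", P, "b")]
        results = run_sign_tests(syns)
        assert [r.domain_id for r in results] == ["a", "b"]
        assert results[0].p_value == 1.0
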