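"""Core domain types for effect direction synthesis.

Effect direction is a standardized metric for systematic reviews in which
effect sizes cannot be pooled: each outcome is recorded only as having
improved (POSITIVE), deteriorated (NEGATIVE) or shown NO_CHANGE after
intervention.  POSITIVE always means *improvement in health*, whatever the
polarity of the underlying measurement — harmonizing polarity (e.g. a lower
symptom score counting as improvement) is the data preparer's job.

These types are deliberately small and immutable; serialization lives in
:mod:`edplot.io` and all computation in the synthesis / sign-test modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence


class Direction(enum.Enum):
    """Direction of an effect.

    Raw outcomes use only POSITIVE / NEGATIVE / NO_CHANGE.  UNCLEAR is a
    domain-level result produced by within-study synthesis when fewer than
    70% of a study's outcomes agree; it is rendered as the sideways arrow
    and is never a valid label for a single raw outcome.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NO_CHANGE = "no_change"
    UNCLEAR = "unclear"


#: Labels permitted on a raw (single-outcome) record.
RAW_DIRECTIONS = frozenset(
    {Direction.POSITIVE, Direction.NEGATIVE, Direction.NO_CHANGE}
)


class Quality(enum.Enum):
    """Three-level critical-appraisal rating mapped to traffic-light shading.

    Exactly three levels are supported because the plot uses exactly three
    row colors (green / yellow / red); other appraisal scales must be mapped
    onto these before input.
    """

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


class SizeClass(enum.Enum):
    """Arrow size class reflecting the intervention-group sample size."""

    SMALL = "small"    # n < 50
    MEDIUM = "medium"  # 50 <= n <= 300, or n unknown
    LARGE = "large"    # n > 300


class Caveat(enum.Enum):
    """Interpretation caveats attached to a cross-study sign test."""

    NO_ELIGIBLE_STUDIES = "no_eligible_studies"
    HIGH_EXCLUSION_FRACTION = "high_exclusion_fraction"
    SMALL_K = "small_k"
    PUBLICATION_BIAS_UNASSESSED = "publication_bias_unassessed"


@dataclass(frozen=True)
class OutcomeRecord:
    """One measured outcome in one study, with its reported effect direction."""

    study_id: str
    domain_id: str
    outcome_name: str
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction not in RAW_DIRECTIONS:
            raise ValueError(
                f"raw outcome {self.outcome_name!r} may not carry direction "
                f"{self.direction.value!r}; UNCLEAR arises only from synthesis"
            )


@dataclass(frozen=True)
class StudyMetadata:
    """Study identity plus the characteristics shown in the plot.

    ``n_intervention`` is the final sample size (individuals) in the
    intervention group; ``None`` records a sample size the review could not
    extract and renders as a medium arrow with an explicit "n unknown" note.
    """

    study_id: str
    design: str = ""
    n_intervention: Optional[int] = None
    quality: Quality = Quality.MODERATE

    def __post_init__(self) -> None:
        if self.n_intervention is not None and self.n_intervention < 0:
            raise ValueError(
                f"study {self.study_id!r}: n_intervention must be >= 0"
            )


@dataclass(frozen=True)
class DomainSynthesis:
    """The within-study, per-domain result of effect direction synthesis."""

    study_id: str
    domain_id: str
    direction: Direction  # POSITIVE | NEGATIVE | UNCLEAR
    n_outcomes: int
    n_positive: int
    n_negative: int
    n_no_change: int
    majority_fraction: Fraction
    size_class: SizeClass
    n_known: bool = True  # False -> render an "n unknown" annotation

    def __post_init__(self) -> None:
        if self.n_outcomes <= 0:
            raise ValueError("a synthesized domain must contain outcomes")
        if self.n_positive + self.n_negative + self.n_no_change != self.n_outcomes:
            raise ValueError("outcome counts must partition n_outcomes")
        if self.direction not in (
            Direction.POSITIVE,
            Direction.NEGATIVE,
            Direction.UNCLEAR,
        ):
            raise ValueError("domain direction must be POSITIVE, NEGATIVE or UNCLEAR")


@dataclass(frozen=True)
class SignTestResult:
    """Cross-study vote counts and exact two-tailed sign test for one domain.

    ``p_value`` is ``None`` when no study contributed a clear direction
    (nothing to test).  The object deliberately exposes no significant-yes/no
    field; see :func:`edplot.signtest.caveat_text`.
    """

    domain_id: str
    n_positive_studies: int
    n_negative_studies: int
    n_excluded_unclear: int
    n_total_studies: int
    p_value: Optional[float]
    caveats: frozenset[Caveat] = frozenset()

    def __post_init__(self) -> None:
        total = (
            self.n_positive_studies
            + self.n_negative_studies
            + self.n_excluded_unclear
        )
        if total != self.n_total_studies:
            raise ValueError("study counts must partition n_total_studies")


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    """All problems found in a dataset, collected rather than raised."""

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, message: str) -> None:
        self.errors.append(ValidationIssue("error", message))

    def warn(self, message: str) -> None:
        self.warnings.append(ValidationIssue("warning", message))

    def __iter__(self):
        return iter(self.errors + self.warnings)


def validate_dataset(
    records: Iterable[OutcomeRecord],
    studies: Iterable[StudyMetadata],
) -> ValidationReport:
    """Check referential integrity and invariants of a long-format dataset.

    Returns a report listing *every* problem found so callers (and the CLI)
    can print them all at once.  Errors: empty identifiers, duplicate
    (study, domain, outcome) triples, duplicate study metadata, and outcome
    records whose study has no metadata.  Warnings: studies absent from some
    domains, and studies with metadata but no outcomes at all.

    Validation is a pure function of the *set* of rows: it is idempotent and
    order-invariant (issues are reported in sorted order).
    """
    records = list(records)
    studies = list(studies)
    report = ValidationReport()

    seen_meta: set[str] = set()
    for s in studies:
        if not s.study_id:
            report.error("study metadata with empty study_id")
        elif s.study_id in seen_meta:
            report.error(f"duplicate study metadata for {s.study_id!r}")
        else:
            seen_meta.add(s.study_id)

    seen_triples: set[tuple[str, str, str]] = set()
    dup_triples: set[tuple[str, str, str]] = set()
    missing_meta: set[str] = set()
    for r in records:
        if not r.study_id:
            report.error(f"outcome {r.outcome_name!r} has empty study_id")
            continue
        if not r.domain_id:
            report.error(
                f"outcome {r.outcome_name!r} in study {r.study_id!r} has "
                "empty domain_id"
            )
            continue
        triple = (r.study_id, r.domain_id, r.outcome_name)
        if triple in seen_triples:
            dup_triples.add(triple)
        seen_triples.add(triple)
        if r.study_id not in seen_meta:
            missing_meta.add(r.study_id)

    for triple in sorted(dup_triples):
        report.error(f"duplicate outcome row {triple!r}")
    for sid in sorted(missing_meta):
        report.error(f"outcome rows reference study {sid!r} with no metadata")

    domains = sorted({r.domain_id for r in records if r.domain_id})
    by_study: dict[str, set[str]] = {}
    for r in records:
        by_study.setdefault(r.study_id, set()).add(r.domain_id)
    for sid in sorted(seen_meta):
        present = by_study.get(sid, set())
        if not present:
            report.warn(f"study {sid!r} has metadata but no outcomes")
            continue
        absent = [d for d in domains if d not in present]
        if absent:
            report.warn(
                f"study {sid!r} has no outcomes in domain(s): "
                + ", ".join(repr(d) for d in absent)
            )
    return report


def canonical_sort(
    records: Sequence[OutcomeRecord],
) -> list[OutcomeRecord]:
    """Canonical row order used for round-trip comparisons and output."""
    return sorted(records, key=lambda r: (r.study_id, r.domain_id, r.outcome_name))
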