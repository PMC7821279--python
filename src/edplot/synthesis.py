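"""Within-study effect direction synthesis.

Each study may measure several conceptually related outcomes (cough
frequency, wheeze, ... -> "respiratory health").  Synthesis collapses them
into one domain-level direction per study: if at least 70% of the outcomes
in the domain agree on POSITIVE (or NEGATIVE), that direction is reported;
otherwise the result is UNCLEAR — no clear effect / conflicting findings,
the sideways arrow.  The 70% comparison is done in exact rational
arithmetic so 7 of 10 passes deterministically (7/10 >= 7/10) and no
floating-point rounding can flip a boundary case.

By default the denominator counts *all* outcomes in the domain, so
NO_CHANGE outcomes dilute both directions (the conservative reading of "70%
of outcomes"); ``denominator="directional"`` restricts the denominator to
outcomes that moved.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Direction,
    DomainSynthesis,
    OutcomeRecord,
    SizeClass,
    StudyMetadata,
)

#: Inclusive majority threshold: >= 70% of outcomes must agree.
MAJORITY_THRESHOLD = Fraction(7, 10)

_DENOMINATORS = ("all", "directional")


def group_outcomes(
    records: Iterable[OutcomeRecord],
) -> dict[tuple[str, str], list[OutcomeRecord]]:
    """Partition outcome records by (study_id, domain_id).

    Every record lands in exactly one group; group order carries no meaning
    and downstream code must be order-invariant.
    """
    groups: dict[tuple[str, str], list[OutcomeRecord]] = {}
    for r in records:
        groups.setdefault((r.study_id, r.domain_id), []).append(r)
    return groups


def arrow_size_class(n_intervention: Optional[int]) -> SizeClass:
    """Map an intervention-group sample size onto the arrow size legend.

    LARGE for n > 300, SMALL for n < 50, MEDIUM for 50 <= n <= 300.
    An unknown sample size (``None``) is rendered MEDIUM; the plot adds an
    explicit "n unknown" annotation rather than dropping the study.
    """
    if n_intervention is None:
        return SizeClass.MEDIUM
    if n_intervention < 0:
        raise ValueError("sample size must be >= 0")
    if n_intervention > 300:
        return SizeClass.LARGE
    if n_intervention < 50:
        return SizeClass.SMALL
    return SizeClass.MEDIUM


def synthesize_domain(
    directions: Sequence[Direction],
    *,
    study_id: str = "",
    domain_id: str = "",
    n_intervention: Optional[int] = None,
    n_known: bool = True,
    denominator: str = "all",
) -> DomainSynthesis:
    """Collapse one study's outcomes in one domain to a single direction.

    Returns POSITIVE if n_positive/denominator >= 7/10, NEGATIVE if
    n_negative/denominator >= 7/10, else UNCLEAR.  A domain in which
    NO_CHANGE outcomes themselves dominate also returns UNCLEAR: the
    sideways arrow covers both "no change" and "conflicting", and the
    per-label counts are retained so renderers can distinguish if desired.

    Raises ``ValueError`` on an empty outcome list (a domain with no
    outcomes should have been rejected by validation).
    """
    if denominator not in _DENOMINATORS:
        raise ValueError(f"denominator must be one of {_DENOMINATORS}")
    directions = list(directions)
    if not directions:
        raise ValueError("domain with no outcomes")
    n_pos = sum(d is Direction.POSITIVE for d in directions)
    n_neg = sum(d is Direction.NEGATIVE for d in directions)
    n_nc = len(directions) - n_pos - n_neg
    if n_pos + n_neg + n_nc != len(directions) or Direction.UNCLEAR in directions:
        raise ValueError("raw outcomes must be POSITIVE/NEGATIVE/NO_CHANGE")

    denom = len(directions) if denominator == "all" else n_pos + n_neg
    if denom == 0:  # directional denominator with only NO_CHANGE outcomes
        majority = Fraction(0)
    else:
        majority = Fraction(max(n_pos, n_neg), denom)

    if denom and Fraction(n_pos, denom) >= MAJORITY_THRESHOLD:
        direction = Direction.POSITIVE
    elif denom and Fraction(n_neg, denom) >= MAJORITY_THRESHOLD:
        direction = Direction.NEGATIVE
    else:
        direction = Direction.UNCLEAR

    return DomainSynthesis(
        study_id=study_id,
        domain_id=domain_id,
        direction=direction,
        n_outcomes=len(directions),
        n_positive=n_pos,
        n_negative=n_neg,
        n_no_change=n_nc,
        majority_fraction=majority,
        size_class=arrow_size_class(n_intervention),
        n_known=n_known,
    )


def synthesize_all(
    records: Iterable[OutcomeRecord],
    studies: Iterable[StudyMetadata],
    *,
    denominator: str = "all",
) -> list[DomainSynthesis]:
    """Run within-study synthesis for every (study, domain) group.

    Results are returned sorted by (study_id, domain_id) so the output is a
    pure, order-invariant function of the input set.
    """
    meta: Mapping[str, StudyMetadata] = {s.study_id: s for s in studies}
    out: list[DomainSynthesis] = []
    for (sid, did), group in sorted(group_outcomes(records).items()):
        if sid not in meta:
            raise KeyError(f"no metadata for study {sid!r}")
        m = meta[sid]
        out.append(
            synthesize_domain(
                [r.direction for r in group],
                study_id=sid,
                domain_id=did,
                n_intervention=m.n_intervention,
                n_known=m.n_intervention is not None,
                denominator=denominator,
            )
        )
    return out
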