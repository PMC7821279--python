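"""Tabular input/output and synthetic-review fixtures.

Input is *long format*: one row per measured outcome, carrying the study
identifier, study characteristics (design, intervention-group final sample
size, quality rating), the outcome domain, the outcome name and the
reported effect direction.  Long format is unambiguous about within-study
multiplicity and machine-friendly; reviews using a wide per-study layout
must be melted first.

Direction and quality tokens are mapped through an explicit vocabulary;
unmapped tokens are errors, never silently coerced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Caveat,
    Direction,
    DomainSynthesis,
    OutcomeRecord,
    Quality,
    SignTestResult,
    SizeClass,
    StudyMetadata,
    ValidationReport,
    canonical_sort,
    validate_dataset,
)
from .signtest import format_p

DEFAULT_DIRECTION_VOCAB: dict[str, Direction] = {
    "positive": Direction.POSITIVE,
    "+": Direction.POSITIVE,
    "up": Direction.POSITIVE,
    "improved": Direction.POSITIVE,
    "negative": Direction.NEGATIVE,
    "-": Direction.NEGATIVE,
    "down": Direction.NEGATIVE,
    "worsened": Direction.NEGATIVE,
    "none": Direction.NO_CHANGE,
    "0": Direction.NO_CHANGE,
    "no change": Direction.NO_CHANGE,
    "null": Direction.NO_CHANGE,
}

DEFAULT_QUALITY_VOCAB: dict[str, Quality] = {
    "high": Quality.HIGH,
    "moderate": Quality.MODERATE,
    "low": Quality.LOW,
}

DEFAULT_COLUMNS: dict[str, str] = {
    "study_id": "study_id",
    "design": "design",
    "n_intervention": "n_intervention",
    "quality": "quality",
    "domain": "domain",
    "outcome": "outcome",
    "direction": "direction",
}


@dataclass(frozen=True)
class InputDialect:
    """Column names and token vocabularies for a long-format input table.

    ``format`` may be "csv", "tsv" or "json"; ``None`` infers it from the
    file extension.  Vocabulary lookup is case-insensitive and strips
    surrounding whitespace before matching.
    """

    format: Optional[str] = None
    columns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    direction_vocab: dict[str, Direction] = field(
        default_factory=lambda: dict(DEFAULT_DIRECTION_VOCAB)
    )
    quality_vocab: dict[str, Quality] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY_VOCAB)
    )


DEFAULT_DIALECT = InputDialect()


class DatasetError(ValueError):
    """Raised when an input file cannot be turned into a valid dataset;
    carries the full list of problems so they can all be printed at once."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


def _infer_format(path: Path, dialect: InputDialect) -> str:
    if dialect.format:
        return dialect.format.lower()
    ext = path.suffix.lower()
    if ext == ".tsv":
        return "tsv"
    if ext == ".json":
        return "json"
    return "csv"


def _norm(token: object) -> str:
    return str(token).strip().lower()


def read_input(
    path,
    dialect: InputDialect = DEFAULT_DIALECT,
) -> tuple[list[OutcomeRecord], list[StudyMetadata]]:
    """Read a long-format review table into validated record collections.

    Raises :class:`DatasetError` listing *every* problem (missing columns,
    unmapped tokens with the offending row, validation failures) rather
    than stopping at the first.
    """
    path = Path(path)
    fmt = _infer_format(path, dialect)
    cols = dialect.columns
    if fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        rows = payload["outcomes"] if isinstance(payload, dict) else payload
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(
            path, sep="\t" if fmt == "tsv" else ",", dtype=str,
            keep_default_na=False,
        )

    problems: list[str] = []
    required = ["study_id", "domain", "outcome", "direction"]
    for key in required:
        if cols[key] not in frame.columns:
            problems.append(f"missing mandatory column {cols[key]!r}")
    if problems:
        raise DatasetError(problems)

    records: list[OutcomeRecord] = []
    meta: dict[str, StudyMetadata] = {}
    meta_conflict: set[str] = set()
    for idx, row in frame.iterrows():
        sid = str(row[cols["study_id"]]).strip()
        token = _norm(row[cols["direction"]])
        direction = dialect.direction_vocab.get(token)
        if direction is None:
            problems.append(
                f"row {idx}: unmapped direction token {row[cols['direction']]!r}"
            )
            continue
        records.append(
            OutcomeRecord(
                study_id=sid,
                domain_id=str(row[cols["domain"]]).strip(),
                outcome_name=str(row[cols["outcome"]]).strip(),
                direction=direction,
            )
        )
        design = str(row.get(cols["design"], "") or "").strip()
        n_raw = str(row.get(cols["n_intervention"], "") or "").strip()
        if n_raw in ("", "na", "NA", "nan"):
            n_int: Optional[int] = None
        else:
            try:
                n_int = int(float(n_raw))
            except ValueError:
                problems.append(
                    f"row {idx}: unparseable sample size {n_raw!r}"
                )
                continue
        q_raw = row.get(cols["quality"], "moderate")
        quality = dialect.quality_vocab.get(_norm(q_raw))
        if quality is None:
            problems.append(f"row {idx}: unmapped quality token {q_raw!r}")
            continue
        m = StudyMetadata(sid, design, n_int, quality)
        if sid in meta and meta[sid] != m:
            meta_conflict.add(sid)
        meta[sid] = m
    for sid in sorted(meta_conflict):
        problems.append(f"conflicting metadata rows for study {sid!r}")

    if problems:
        raise DatasetError(problems)

    report = validate_dataset(records, meta.values())
    if not report.ok:
        raise DatasetError([i.message for i in report.errors])
    return canonical_sort(records), sorted(meta.values(), key=lambda s: s.study_id)


def write_dataset(
    records: Iterable[OutcomeRecord],
    studies: Iterable[StudyMetadata],
    path,
    dialect: InputDialect = DEFAULT_DIALECT,
) -> None:
    """Write a dataset back to disk in canonical long-format order."""
    path = Path(path)
    fmt = _infer_format(path, dialect)
    meta = {s.study_id: s for s in studies}
    cols = dialect.columns
    rows = []
    for r in canonical_sort(list(records)):
        m = meta[r.study_id]
        rows.append(
            {
                cols["study_id"]: r.study_id,
                cols["design"]: m.design,
                cols["n_intervention"]: (
                    "" if m.n_intervention is None else m.n_intervention
                ),
                cols["quality"]: m.quality.value,
                cols["domain"]: r.domain_id,
                cols["outcome"]: r.outcome_name,
                cols["direction"]: r.direction.value.replace("_", " "),
            }
        )
    if fmt == "json":
        path.write_text(
            json.dumps({"outcomes": rows}, indent=1, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
    else:
        pd.DataFrame(rows).to_csv(
            path, index=False, sep="\t" if fmt == "tsv" else ","
        )


def _synthesis_row(s: DomainSynthesis) -> dict:
    return {
        "row_type": "synthesis",
        "study_id": s.study_id,
        "domain": s.domain_id,
        "direction": s.direction.value,
        "n_outcomes": s.n_outcomes,
        "n_positive": s.n_positive,
        "n_negative": s.n_negative,
        "n_no_change": s.n_no_change,
        "majority_fraction": str(s.majority_fraction),
        "size_class": s.size_class.value,
        "n_known": s.n_known,
    }


def _sign_test_row(t: SignTestResult) -> dict:
    return {
        "row_type": "sign_test",
        "domain": t.domain_id,
        "n_positive_studies": t.n_positive_studies,
        "n_negative_studies": t.n_negative_studies,
        "n_excluded_unclear": t.n_excluded_unclear,
        "n_total_studies": t.n_total_studies,
        "p_value": t.p_value,
        "p_display": format_p(t.p_value),
        "caveats": sorted(c.value for c in t.caveats),
    }


def write_results(
    syntheses: Iterable[DomainSynthesis],
    sign_tests: Iterable[SignTestResult],
    path,
    format: Optional[str] = None,
) -> None:
    """Write per-(study, domain) syntheses and per-domain sign tests.

    CSV output interleaves both row kinds under a ``row_type`` column
    (caveat sets joined with ``|``); JSON keeps them as two lists and is
    loss-free (see :func:`read_results`).
    """
    path = Path(path)
    fmt = (format or ("json" if path.suffix.lower() == ".json" else "csv")).lower()
    syn_rows = [_synthesis_row(s) for s in syntheses]
    test_rows = [_sign_test_row(t) for t in sign_tests]
    if fmt == "json":
        path.write_text(
            json.dumps(
                {"syntheses": syn_rows, "sign_tests": test_rows},
                indent=1,
                ensure_ascii=False,
            )
            + "\n",
            encoding="utf-8",
        )
        return
    for row in test_rows:
        row["caveats"] = "|".join(row["caveats"])
    fields = [
        "row_type", "study_id", "domain", "direction", "n_outcomes",
        "n_positive", "n_negative", "n_no_change", "majority_fraction",
        "size_class", "n_known", "n_positive_studies", "n_negative_studies",
        "n_excluded_unclear", "n_total_studies", "p_value", "p_display",
        "caveats",
    ]
    frame = pd.DataFrame(syn_rows + test_rows, columns=fields)
    frame.to_csv(path, index=False)


def read_results(path) -> tuple[list[DomainSynthesis], list[SignTestResult]]:
    """Reparse a JSON results file back into in-memory result objects."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    syntheses = [
        DomainSynthesis(
            study_id=r["study_id"],
            domain_id=r["domain"],
            direction=Direction(r["direction"]),
            n_outcomes=r["n_outcomes"],
            n_positive=r["n_positive"],
            n_negative=r["n_negative"],
            n_no_change=r["n_no_change"],
            majority_fraction=Fraction(r["majority_fraction"]),
            size_class=SizeClass(r["size_class"]),
            n_known=r["n_known"],
        )
        for r in payload["syntheses"]
    ]
    tests = [
        SignTestResult(
            domain_id=r["domain"],
            n_positive_studies=r["n_positive_studies"],
            n_negative_studies=r["n_negative_studies"],
            n_excluded_unclear=r["n_excluded_unclear"],
            n_total_studies=r["n_total_studies"],
            p_value=r["p_value"],
            caveats=frozenset(Caveat(c) for c in r["caveats"]),
        )
        for r in payload["sign_tests"]
    ]
    return syntheses, tests


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_fixture(
    n_studies: int = 10,
    domains: Sequence[str] = ("domain_a", "domain_b"),
    outcomes_per_domain_range: tuple[int, int] = (1, 4),
    direction_probabilities: tuple[float, float, float] = (0.6, 0.2, 0.2),
    quality_distribution: tuple[float, float, float] = (0.3, 0.5, 0.2),
    n_range: tuple[int, int] = (20, 500),
    p_domain_missing: float = 0.0,
    seed: int = 0,
) -> tuple[list[OutcomeRecord], list[StudyMetadata]]:
    """Generate a reproducible synthetic review table.

    ``direction_probabilities`` are (positive, negative, no-change) for each
    raw outcome; ``quality_distribution`` is (high, moderate, low).  Each
    study-domain pair is independently dropped with ``p_domain_missing`` to
    emulate studies that did not report a domain.  Output always passes
    :func:`~edplot.model.validate_dataset`.
    """
    if abs(sum(direction_probabilities) - 1.0) > 1e-9:
        raise ValueError("direction probabilities must sum to 1")
    if abs(sum(quality_distribution) - 1.0) > 1e-9:
        raise ValueError("quality distribution must sum to 1")
    lo, hi = outcomes_per_domain_range
    if lo < 1 or hi < lo:
        raise ValueError("outcomes_per_domain_range must be 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    directions = [Direction.POSITIVE, Direction.NEGATIVE, Direction.NO_CHANGE]
    qualities = [Quality.HIGH, Quality.MODERATE, Quality.LOW]
    designs = ["RCT", "controlled before-after", "uncontrolled before-after"]

    studies: list[StudyMetadata] = []
    records: list[OutcomeRecord] = []
    width = len(str(n_studies))
    for i in range(n_studies):
        sid = f"S{i + 1:0{width}d}"
        studies.append(
            StudyMetadata(
                study_id=sid,
                design=designs[int(rng.integers(len(designs)))],
                n_intervention=int(rng.integers(n_range[0], n_range[1] + 1)),
                quality=qualities[int(rng.choice(3, p=quality_distribution))],
            )
        )
        for domain in domains:
            if rng.random() < p_domain_missing:
                continue
            k = int(rng.integers(lo, hi + 1))
            for j in range(k):
                records.append(
                    OutcomeRecord(
                        study_id=sid,
                        domain_id=domain,
                        outcome_name=f"{domain}_outcome_{j + 1}",
                        direction=directions[
                            int(rng.choice(3, p=direction_probabilities))
                        ],
                    )
                )
    # guarantee at least one outcome per study so validation stays clean
    for s in studies:
        if not any(r.study_id == s.study_id for r in records):
            records.append(
                OutcomeRecord(s.study_id, domains[0], f"{domains[0]}_outcome_1",
                              Direction.POSITIVE)
            )
    return canonical_sort(records), studies


# Synthetic stand-in for the warmth/energy-efficiency housing review: the
# published account prints only domain-level vote counts (housing condition
# 9 positive / 1 unclear of 10; general health 5 positive / 1 negative /
# 1 unclear of 7 reporting; respiratory health 5 positive / 1 negative /
# 4 unclear of 10), so the per-study outcome lists below are invented to
# synthesize to exactly those counts under the 70% rule.
_HOUSING_STUDIES = [
    #  id    design                        n     quality
    ("S01", "RCT", 420, Quality.HIGH),
    ("S02", "controlled before-after", 120, Quality.MODERATE),
    ("S03", "RCT", 35, Quality.HIGH),
    ("S04", "uncontrolled before-after", 310, Quality.MODERATE),
    ("S05", "controlled before-after", 60, Quality.LOW),
    ("S06", "controlled before-after", 85, Quality.MODERATE),
    ("S07", "uncontrolled before-after", None, Quality.MODERATE),
    ("S08", "RCT", 500, Quality.HIGH),
    ("S09", "uncontrolled before-after", 45, Quality.LOW),
    ("S10", "controlled before-after", 150, Quality.MODERATE),
]

_P, _N, _Z = Direction.POSITIVE, Direction.NEGATIVE, Direction.NO_CHANGE

_HOUSING_OUTCOMES: dict[str, dict[str, list[Direction]]] = {
    # 9 positive studies, S10 unclear -> votes (9, 0, 1)
    "housing_condition": {
        "S01": [_P, _P, _P],
        "S02": [_P],
        "S03": [_P, _P],
        "S04": [_P] * 7 + [_N] * 3,  # 7/10 meets the 70% rule exactly
        "S05": [_P],
        "S06": [_P, _P],
        "S07": [_P],
        "S08": [_P, _P, _P],
        "S09": [_P],
        "S10": [_P, _N],
    },
    # 7 studies report; votes (5, 1, 1); S08-S10 have no data here
    "general_health": {
        "S01": [_P, _P],
        "S02": [_P],
        "S03": [_P],
        "S04": [_P],
        "S05": [_P, _P, _P],
        "S06": [_N, _N],
        "S07": [_P, _N, _Z],
    },
    # votes (5, 1, 4)
    "respiratory_health": {
        "S01": [_P, _P, _P, _P],
        "S02": [_P],
        "S03": [_P, _P, _P],
        "S04": [_P],
        "S05": [_P, _P],
        "S06": [_N],
        "S07": [_P, _N],
        "S08": [_P, _P, _N, _N],
        "S09": [_Z],  # unanimous no-change still renders the sideways arrow
        "S10": [_P, _N, _N],
    },
}

_OUTCOME_NAMES = {
    "housing_condition": "condition",
    "general_health": "health",
    "respiratory_health": "respiratory",
}

HOUSING_DOMAINS = tuple(_HOUSING_OUTCOMES)


def housing_example() -> tuple[list[OutcomeRecord], list[StudyMetadata]]:
    """The packaged synthetic warmth/energy-efficiency review preset.

    Piped through synthesis and the sign test it reproduces the printed
    domain-level vote counts and p-values (.0039, .2188, .2188).
    """
    studies = [StudyMetadata(*row) for row in _HOUSING_STUDIES]
    records: list[OutcomeRecord] = []
    for domain, per_study in _HOUSING_OUTCOMES.items():
        stem = _OUTCOME_NAMES[domain]
        for sid, dirs in per_study.items():
            for j, d in enumerate(dirs):
                records.append(
                    OutcomeRecord(sid, domain, f"{stem}_{j + 1}", d)
                )
    return canonical_sort(records), studies


def housing_example_path() -> Path:
    """Path of the packaged CSV copy of the housing preset."""
    return Path(
        resources.files("edplot").joinpath("data/housing_example.csv")
    )
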