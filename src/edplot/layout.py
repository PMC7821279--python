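"""Grid layout for the effect direction plot.

The plot is a table: one row per study (shaded by quality), leading columns
of study characteristics, then one column per outcome domain whose cells
hold a direction arrow sized by the intervention-group sample size, with a
subscript giving the number of outcomes the arrow summarizes.  This module
produces the laid-out :class:`EDPlotSpec`; actual drawing lives in
:mod:`edplot.render`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import Direction, DomainSynthesis, Quality, SizeClass, StudyMetadata

#: Arrow glyphs exactly as used in the plot template.  The sideways arrow is
#: the two-character sequence, not a single bidirectional-arrow codepoint.
GLYPHS = {
    Direction.POSITIVE: "▲",   # ▲
    Direction.NEGATIVE: "▼",   # ▼
    Direction.UNCLEAR: "◂▸",  # ◂▸
}

#: Traffic-light row shading (fill colors; rendered at reduced opacity).
DEFAULT_PALETTE = {
    Quality.HIGH: "#2E7D32",      # green
    Quality.MODERATE: "#F9A825",  # yellow/amber
    Quality.LOW: "#C62828",       # red
}

#: Colorblind-safe alternative (Okabe-Ito hues); the renderer adds pattern
#: fills so quality remains distinguishable without color.
COLORBLIND_PALETTE = {
    Quality.HIGH: "#0072B2",
    Quality.MODERATE: "#E69F00",
    Quality.LOW: "#CC79A7",
}

LEGEND_TEXT = (
    "▲ positive health impact  ▼ negative health impact  "
    "◂▸ no change / mixed effects / conflicting findings. "
    "Arrow size: large n>300, medium n 50-300, small n<50 "
    "(final intervention-group sample size); subscript = number of "
    "outcomes summarized. Row shading: high quality / low risk of bias; "
    "moderate / some concerns; low quality / high risk of bias."
)


@dataclass(frozen=True)
class Cell:
    """One study-domain cell; ``empty`` cells are explicit, never skipped."""

    glyph: str = ""
    size_class: Optional[SizeClass] = None
    subscript: Optional[int] = None
    n_unknown: bool = False
    empty: bool = True


@dataclass
class EDPlotSpec:
    """The laid-out plot grid, ready for deterministic rendering."""

    rows: list[tuple[StudyMetadata, str]]  # (study, shading color)
    characteristic_columns: list[tuple[str, tuple[str, ...]]]
    domain_columns: list[tuple[str, str]]  # (domain_id, display label)
    cells: dict[tuple[str, str], Cell]
    legend: str = LEGEND_TEXT
    title: str = ""
    colorblind: bool = False
    footer: list[str] = field(default_factory=list)


def _display_label(domain_id: str) -> str:
    return domain_id.replace("_", " ").strip()


def layout_plot(
    studies: Sequence[StudyMetadata],
    syntheses: Iterable[DomainSynthesis],
    *,
    characteristic_columns: Optional[Mapping[str, Mapping[str, str]]] = None,
    domain_order: Optional[Sequence[str]] = None,
    domain_labels: Optional[Mapping[str, str]] = None,
    sort_rows: bool = False,
    colorblind: bool = False,
    title: str = "",
) -> EDPlotSpec:
    """Arrange studies and their domain syntheses into the plot grid.

    Row order follows the input order of ``studies`` unless ``sort_rows``
    requests sorting by quality (high first), then study_id.  Every
    (study, domain) pair receives exactly one cell; pairs without data get
    an explicit empty cell.  ``characteristic_columns`` maps a column label
    to a per-study text mapping (missing studies render blank).

    Raises ``KeyError`` if a synthesis references a study absent from
    ``studies``.
    """
    studies = list(studies)
    syntheses = list(syntheses)
    known = {s.study_id for s in studies}
    for syn in syntheses:
        if syn.study_id not in known:
            raise KeyError(
                f"synthesis references study {syn.study_id!r} with no metadata"
            )

    if sort_rows:
        order = {Quality.HIGH: 0, Quality.MODERATE: 1, Quality.LOW: 2}
        studies = sorted(studies, key=lambda s: (order[s.quality], s.study_id))

    palette = COLORBLIND_PALETTE if colorblind else DEFAULT_PALETTE
    rows = [(s, palette[s.quality]) for s in studies]

    if domain_order is None:
        domain_order = sorted({s.domain_id for s in syntheses})
    labels = domain_labels or {}
    domain_columns = [
        (d, labels.get(d, _display_label(d))) for d in domain_order
    ]

    by_key = {(s.study_id, s.domain_id): s for s in syntheses}
    if len(by_key) != len(syntheses):
        raise ValueError("duplicate synthesis for a (study, domain) pair")

    cells: dict[tuple[str, str], Cell] = {}
    for study, _ in rows:
        for domain_id, _ in domain_columns:
            syn = by_key.get((study.study_id, domain_id))
            if syn is None:
                cells[(study.study_id, domain_id)] = Cell()
            else:
                cells[(study.study_id, domain_id)] = Cell(
                    glyph=GLYPHS[syn.direction],
                    size_class=syn.size_class,
                    subscript=syn.n_outcomes if syn.n_outcomes > 1 else None,
                    n_unknown=not syn.n_known,
                    empty=False,
                )

    char_cols: list[tuple[str, tuple[str, ...]]] = []
    if characteristic_columns:
        for label, per_study in characteristic_columns.items():
            char_cols.append(
                (label, tuple(per_study.get(s.study_id, "") for s, _ in rows))
            )

    return EDPlotSpec(
        rows=rows,
        characteristic_columns=char_cols,
        domain_columns=domain_columns,
        cells=cells,
        colorblind=colorblind,
        title=title,
    )
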