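"""Deterministic SVG (and matplotlib-backed PNG) rendering of the plot.

The SVG is assembled as plain text with a fixed element order and fixed
number formatting, so an identical :class:`~edplot.layout.EDPlotSpec`
always yields byte-identical output — a property the test suite holds the
renderer to.  Layout metrics and glyph sizes are configurable but carry
sensible defaults; the legend is always emitted so every plot is
self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
from xml.sax.saxutils import escape

from .layout import EDPlotSpec, Cell
from .model import Quality, SizeClass
from .signtest import SignTestResult, format_p

#: Arrow glyph font sizes (pt) for the three size classes.
DEFAULT_GLYPH_SIZES = {
    SizeClass.SMALL: 10,
    SizeClass.MEDIUM: 14,
    SizeClass.LARGE: 19,
}

_RENDERER_VERSION = "edplot-svg-1"


@dataclass(frozen=True)
class RenderOptions:
    cell_width: int = 96
    char_width: int = 110
    study_width: int = 120
    row_height: int = 34
    header_height: int = 40
    margin: int = 12
    font_family: str = "DejaVu Sans, sans-serif"
    font_size: int = 11
    shade_opacity: float = 0.25
    glyph_sizes: Optional[dict[SizeClass, int]] = None

    def sizes(self) -> dict[SizeClass, int]:
        return self.glyph_sizes or DEFAULT_GLYPH_SIZES


# pattern fills keyed by quality, used only in colorblind mode so shading is
# readable without color discrimination
_PATTERNS = {
    Quality.HIGH: (
        '<pattern id="pat-high" width="8" height="8" patternUnits="userSpaceOnUse">'
        '<path d="M0,8 L8,0" stroke="#555555" stroke-width="1"/></pattern>'
    ),
    Quality.MODERATE: (
        '<pattern id="pat-moderate" width="8" height="8" patternUnits="userSpaceOnUse">'
        '<circle cx="4" cy="4" r="1.2" fill="#555555"/></pattern>'
    ),
    Quality.LOW: (
        '<pattern id="pat-low" width="8" height="8" patternUnits="userSpaceOnUse">'
        '<path d="M0,0 L8,8" stroke="#555555" stroke-width="1"/>'
        '<path d="M0,8 L8,0" stroke="#555555" stroke-width="1"/></pattern>'
    ),
}


def _cell_markup(
    cell: Cell, cx: float, cy: float, opts: RenderOptions
) -> list[str]:
    parts = [f'<g class="domain-cell">']
    if not cell.empty:
        size = opts.sizes()[cell.size_class]
        parts.append(
            f'<text x="{cx:.1f}" y="{cy:.1f}" text-anchor="middle" '
            f'dominant-baseline="middle" font-size="{size}">'
            f"{escape(cell.glyph)}</text>"
        )
        if cell.subscript is not None:
            parts.append(
                f'<text x="{cx + size * 0.75:.1f}" y="{cy + size * 0.35:.1f}" '
                f'font-size="{max(7, size // 2)}">{cell.subscript}</text>'
            )
        if cell.n_unknown:
            parts.append(
                f'<text x="{cx:.1f}" y="{cy + opts.row_height * 0.38:.1f}" '
                f'text-anchor="middle" font-size="7">n unknown</text>'
            )
    parts.append("</g>")
    return parts


def render_svg(
    spec: EDPlotSpec,
    options: Optional[RenderOptions] = None,
    sign_tests: Optional[list[SignTestResult]] = None,
) -> str:
    """Render the laid-out plot to an SVG 1.1 document string.

    ``sign_tests``, when given, adds a footer row per domain with vote
    counts and the display-rounded p-value (off by default — the canonical
    plot carries no test results).
    """
    opts = options or RenderOptions()
    n_rows = len(spec.rows)
    n_char = len(spec.characteristic_columns)
    n_dom = len(spec.domain_columns)

    footer_lines: list[str] = list(spec.footer)
    if sign_tests:
        by_domain = {t.domain_id: t for t in sign_tests}
        for domain_id, label in spec.domain_columns:
            t = by_domain.get(domain_id)
            if t is None:
                continue
            footer_lines.append(
                f"{label}: {t.n_positive_studies}+ / {t.n_negative_studies}- "
                f"({t.n_excluded_unclear} unclear excluded), "
                f"p = {format_p(t.p_value)}"
                + ("" if not t.caveats else " [" + ", ".join(
                    sorted(c.value for c in t.caveats)) + "]")
            )

    grid_left = opts.margin + opts.study_width + n_char * opts.char_width
    width = grid_left + n_dom * opts.cell_width + opts.margin
    legend_height = 3 * (opts.font_size + 4)
    footer_height = len(footer_lines) * (opts.font_size + 4)
    title_height = opts.row_height if spec.title else 0
    height = (
        opts.margin + title_height + opts.header_height
        + n_rows * opts.row_height + footer_height + legend_height
        + 2 * opts.margin
    )

    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'font-family="{escape(spec_font(opts))}" font-size="{opts.font_size}" '
        f'data-renderer="{_RENDERER_VERSION}">'
    )
    if spec.colorblind:
        out.append("<defs>" + "".join(_PATTERNS[q] for q in Quality) + "</defs>")

    y0 = opts.margin + title_height
    if spec.title:
        out.append(
            f'<text x="{opts.margin}" y="{opts.margin + opts.font_size + 2}" '
            f'font-size="{opts.font_size + 3}" font-weight="bold">'
            f"{escape(spec.title)}</text>"
        )

    # header row
    hy = y0 + opts.header_height - 10
    out.append(
        f'<text x="{opts.margin + 4}" y="{hy}" font-weight="bold">Study</text>'
    )
    x = opts.margin + opts.study_width
    for label, _ in spec.characteristic_columns:
        out.append(
            f'<text x="{x + 4}" y="{hy}" font-weight="bold">{escape(label)}</text>'
        )
        x += opts.char_width
    for i, (_, label) in enumerate(spec.domain_columns):
        cx = grid_left + i * opts.cell_width + opts.cell_width / 2
        out.append(
            f'<text x="{cx:.1f}" y="{hy}" text-anchor="middle" '
            f'font-weight="bold">{escape(label)}</text>'
        )

    # study rows: shaded background, characteristics, domain cells
    for r, (study, color) in enumerate(spec.rows):
        ry = y0 + opts.header_height + r * opts.row_height
        out.append(
            f'<rect class="row-bg" x="{opts.margin}" y="{ry}" '
            f'width="{width - 2 * opts.margin}" height="{opts.row_height}" '
            f'fill="{color}" fill-opacity="{opts.shade_opacity}"/>'
        )
        if spec.colorblind:
            out.append(
                f'<rect x="{opts.margin}" y="{ry}" '
                f'width="{width - 2 * opts.margin}" height="{opts.row_height}" '
                f'fill="url(#pat-{study.quality.value})" fill-opacity="0.35"/>'
            )
        ty = ry + opts.row_height / 2
        out.append(
            f'<text x="{opts.margin + 4}" y="{ty:.1f}" '
            f'dominant-baseline="middle">{escape(study.study_id)}</text>'
        )
        x = opts.margin + opts.study_width
        for _, values in spec.characteristic_columns:
            out.append(
                f'<text x="{x + 4}" y="{ty:.1f}" dominant-baseline="middle">'
                f"{escape(values[r])}</text>"
            )
            x += opts.char_width
        for i, (domain_id, _) in enumerate(spec.domain_columns):
            cx = grid_left + i * opts.cell_width + opts.cell_width / 2
            cell = spec.cells[(study.study_id, domain_id)]
            out.extend(_cell_markup(cell, cx, ty, opts))

    # grid lines for readability (drawn after fills, before footer)
    table_bottom = y0 + opts.header_height + n_rows * opts.row_height
    for i in range(n_dom + 1):
        gx = grid_left + i * opts.cell_width
        out.append(
            f'<line x1="{gx}" y1="{y0}" x2="{gx}" y2="{table_bottom}" '
            f'stroke="#999999" stroke-width="0.5"/>'
        )

    fy = table_bottom + opts.font_size + 4
    for line in footer_lines:
        out.append(
            f'<text x="{opts.margin + 4}" y="{fy}" font-size="{opts.font_size - 1}">'
            f"{escape(line)}</text>"
        )
        fy += opts.font_size + 4

    # legend, wrapped onto three fixed lines
    words = spec.legend.split(" ")
    third = (len(words) + 2) // 3
    for chunk_i in range(3):
        chunk = " ".join(words[chunk_i * third:(chunk_i + 1) * third])
        if not chunk:
            continue
        out.append(
            f'<text x="{opts.margin + 4}" y="{fy}" font-size="{opts.font_size - 2}" '
            f'fill="#333333">{escape(chunk)}</text>'
        )
        fy += opts.font_size + 4

    out.append("</svg>")
    return "\n".join(out) + "\n"


def spec_font(opts: RenderOptions) -> str:
    return opts.font_family


def render_png(
    spec: EDPlotSpec,
    path,
    options: Optional[RenderOptions] = None,
    dpi: int = 150,
) -> None:
    """Draw the plot with matplotlib and save a PNG at the given DPI.

    The PNG mirrors the SVG layout (rows, shading, arrows with three glyph
    sizes, subscripts, legend) but is rasterized by matplotlib rather than
    converted from the SVG text.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    opts = options or RenderOptions()
    n_rows = len(spec.rows)
    n_char = len(spec.characteristic_columns)
    n_dom = len(spec.domain_columns)
    n_cols = 1 + n_char + n_dom

    fig_w = max(6.0, 1.1 * n_cols)
    fig_h = max(3.0, 0.45 * (n_rows + 4))
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    ax.set_xlim(0, n_cols)
    ax.set_ylim(-1.5, n_rows + 1)
    ax.axis("off")

    headers = (
        ["Study"]
        + [label for label, _ in spec.characteristic_columns]
        + [label for _, label in spec.domain_columns]
    )
    for c, h in enumerate(headers):
        ax.text(c + 0.5, n_rows + 0.5, h, ha="center", va="center",
                fontweight="bold", fontsize=9)

    glyph_pts = opts.sizes()
    for r, (study, color) in enumerate(spec.rows):
        y = n_rows - 1 - r
        ax.axhspan(y, y + 1, xmin=0, xmax=1, color=color,
                   alpha=opts.shade_opacity, zorder=0)
        ax.text(0.5, y + 0.5, study.study_id, ha="center", va="center",
                fontsize=8)
        for c, (_, values) in enumerate(spec.characteristic_columns):
            ax.text(1 + c + 0.5, y + 0.5, values[r], ha="center",
                    va="center", fontsize=8)
        for c, (domain_id, _) in enumerate(spec.domain_columns):
            cell = spec.cells[(study.study_id, domain_id)]
            if cell.empty:
                continue
            x = 1 + n_char + c + 0.5
            size = glyph_pts[cell.size_class]
            ax.text(x, y + 0.5, cell.glyph, ha="center", va="center",
                    fontsize=size)
            if cell.subscript is not None:
                ax.text(x + 0.22, y + 0.32, str(cell.subscript),
                        ha="left", va="center", fontsize=max(6, size // 2))
            if cell.n_unknown:
                ax.text(x, y + 0.12, "n unknown", ha="center", va="center",
                        fontsize=5)

    ax.text(0.02, -0.8, spec.legend, fontsize=6, wrap=True,
            transform=ax.transData)
    if spec.title:
        ax.set_title(spec.title, fontsize=11)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
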