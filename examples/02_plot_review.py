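"""Render the effect direction plot for a review.

Lays out one row per study (shaded green/yellow/red by quality) and one
column per outcome domain, with direction arrows sized by the
intervention-group sample size and subscripted by the number of outcomes
each arrow summarizes.  Writes both SVG and PNG.
"""

from edplot import layout_plot, render_png, render_svg, synthesize_all
from edplot.io import housing_example

records, studies = housing_example()
syntheses = synthesize_all(records, studies)

spec = layout_plot(
    studies,
    syntheses,
    characteristic_columns={
        "Design": {s.study_id: s.design for s in studies},
        "n (intervention)": {
            s.study_id: "unknown" if s.n_intervention is None
            else str(s.n_intervention)
            for s in studies
        },
    },
    title="Warmth and energy efficiency improvements: health impacts",
)

svg = render_svg(spec)
with open("housing_plot.svg", "w", encoding="utf-8") as fh:
    fh.write(svg)
render_png(spec, "housing_plot.png", dpi=150)

print(f"wrote housing_plot.svg ({len(svg)} bytes) and housing_plot.png")
print(f"rows: {len(spec.rows)}, domain columns: {len(spec.domain_columns)}")
# 10 rows x 3 domains = 30 cells; empty cells (studies not reporting a
# domain) are drawn explicitly so no study silently disappears.
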