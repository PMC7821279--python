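"""Plot layout and deterministic SVG / PNG rendering."""

import pytest

from edplot import (
    Direction,
    Quality,
    StudyMetadata,
    layout_plot,
    render_png,
    render_svg,
    synthesize_all,
    synthesize_domain,
)
from edplot.io import generate_fixture
from edplot.layout import COLORBLIND_PALETTE, DEFAULT_PALETTE, GLYPHS


def syn(study, labels, domain="dom", n=None):
    return synthesize_domain(labels, study_id=study, domain_id=domain,
                             n_intervention=n, n_known=n is not None)


P, N, Z = Direction.POSITIVE, Direction.NEGATIVE, Direction.NO_CHANGE


@pytest.fixture
def small_spec():
    studies = [
        StudyMetadata("S1", "RCT", 400, Quality.HIGH),
        StudyMetadata("S2", "cohort", 80, Quality.MODERATE),
        StudyMetadata("S3", "cohort", None, Quality.LOW),
    ]
    syntheses = [
        syn("S1", [P, P, P], n=400),
        syn("S2", [N, N], n=80),
        syn("S3", [P, N]),
    ]
    return studies, syntheses


class TestLayout:
    def test_glyphs_subscripts_and_shading(self, small_spec):
        studies, syntheses = small_spec
        spec = layout_plot(studies, syntheses)
        c1 = spec.cells[("S1", "dom")]
        assert c1.glyph == "▲" and c1.subscript == 3
        c2 = spec.cells[("S2", "dom")]
        assert c2.glyph == "▼" and c2.subscript == 2
        c3 = spec.cells[("S3", "dom")]
        assert c3.glyph == "◂▸" and c3.n_unknown
        assert [color for _, color in spec.rows] == [
            DEFAULT_PALETTE[Quality.HIGH],
            DEFAULT_PALETTE[Quality.MODERATE],
            DEFAULT_PALETTE[Quality.LOW],
        ]

    def test_single_outcome_cell_has_no_subscript(self):
        spec = layout_plot([StudyMetadata("S1")], [syn("S1", [P])])
        assert spec.cells[("S1", "dom")].subscript is None

    def test_missing_pair_is_explicit_empty_cell(self, small_spec):
        studies, syntheses = small_spec
        spec = layout_plot(studies, syntheses + [syn("S1", [P], domain="other")])
        assert spec.cells[("S2", "other")].empty
        assert not spec.cells[("S1", "other")].empty
        assert len(spec.cells) == 3 * 2

    def test_unknown_study_raises(self, small_spec):
        studies, syntheses = small_spec
        with pytest.raises(KeyError, match="S4"):
            layout_plot(studies, syntheses + [syn("S4", [P])])

    def test_sort_rows_by_quality_then_id(self, small_spec):
        studies, syntheses = small_spec
        spec = layout_plot(list(reversed(studies)), syntheses, sort_rows=True)
        assert [s.study_id for s, _ in spec.rows] == ["S1", "S2", "S3"]

    def test_characteristic_columns_follow_row_order(self, small_spec):
        studies, syntheses = small_spec
        spec = layout_plot(
            studies, syntheses,
            characteristic_columns={"Design": {"S1": "RCT", "S3": "cohort"}},
        )
        label, values = spec.characteristic_columns[0]
        assert label == "Design"
        assert values == ("RCT", "", "cohort")


class TestRenderSVG:
    def test_identical_spec_renders_identical_bytes(self, small_spec):
        spec = layout_plot(*small_spec)
        assert render_svg(spec).encode() == render_svg(spec).encode()

    def test_glyph_size_mapping(self, small_spec):
        svg = render_svg(layout_plot(*small_spec))
        assert 'font-size="19">▲' in svg           # LARGE (n=400)
        assert 'font-size="14">▼' in svg           # MEDIUM (n=80)
        assert 'font-size="14">◂▸' in svg          # unknown n -> MEDIUM
        assert "n unknown" in svg

    def test_small_size_class_uses_smallest_glyph(self):
        spec = layout_plot(
            [StudyMetadata("S1", "RCT", 10, Quality.HIGH)],
            [syn("S1", [P], n=10)],
        )
        assert 'font-size="10">▲' in render_svg(spec)

    def test_grid_completeness_on_random_fixtures(self):
        for seed in (0, 1, 2):
            records, studies = generate_fixture(
                n_studies=6, domains=("a", "b", "c", "d"), seed=seed
            )
            syntheses = synthesize_all(records, studies)
            svg = render_svg(layout_plot(studies, syntheses))
            assert svg.count('class="domain-cell"') == 6 * 4
            assert svg.count('class="row-bg"') == 6

    def test_row_fill_matches_quality_palette(self, small_spec):
        svg = render_svg(layout_plot(*small_spec))
        for q in Quality:
            assert f'fill="{DEFAULT_PALETTE[q]}"' in svg

    def test_only_direction_glyphs_in_cells(self):
        records, studies = generate_fixture(n_studies=5, domains=("a", "b"),
                                            seed=4)
        syntheses = synthesize_all(records, studies)
        spec = layout_plot(studies, syntheses)
        for cell in spec.cells.values():
            assert cell.empty or cell.glyph in set(GLYPHS.values())

    def test_colorblind_palette_swap(self, small_spec):
        studies, syntheses = small_spec
        svg = render_svg(layout_plot(studies, syntheses, colorblind=True))
        for q in Quality:
            assert DEFAULT_PALETTE[q] not in svg
            assert COLORBLIND_PALETTE[q] in svg
        assert "pat-high" in svg  # pattern fills accompany the palette

    def test_legend_always_present(self, small_spec):
        svg = render_svg(layout_plot(*small_spec))
        assert "positive health impact" in svg

    def test_sign_test_footer_optional(self, small_spec):
        from edplot import run_sign_tests
        studies, syntheses = small_spec
        spec = layout_plot(studies, syntheses)
        plain = render_svg(spec)
        with_footer = render_svg(spec, sign_tests=run_sign_tests(syntheses))
        assert "p = " not in plain
        assert "1+ / 1- (1 unclear excluded), p = 1.0000" in with_footer


def test_render_png_writes_file(tmp_path, small_spec):
    spec = layout_plot(*small_spec)
    out = tmp_path / "plot.png"
    render_png(spec, out, dpi=72)
    assert out.stat().st_size > 0
    assert out.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"
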