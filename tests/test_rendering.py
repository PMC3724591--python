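"""Track layout, deterministic SVG rendering, zoom and stacking."""

import pytest

from lolliprot import (
    DomainAnnotation,
    MutationRecord,
    PlotSpec,
    ProteinContext,
    PTMSite,
    RenderConfig,
    conservation_scores,
    count_svg_ids,
    layout,
    list_svg_ids,
    load_config,
    men2a_like_subset,
    render,
    zoom_view,
)

from conftest import make_alignment


def _mut(position, ref="C", alt="R"):
    return MutationRecord("P", "G", position, ref, alt)


def _minimal_spec(**overrides):
    defaults = dict(
        context=ProteinContext(length=100, query_name="toy"),
        mutations_primary=[_mut(10), _mut(50)],
    )
    defaults.update(overrides)
    return PlotSpec(**defaults)


def _profile(length=100):
    ref = ("ACDEFGHIKL" * (length // 10 + 1))[:length]
    return conservation_scores(make_alignment({"ref": ref, "b": ref, "c": "M" * length}))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def test_minimal_layout_has_exactly_four_bands():
    lay = layout(_minimal_spec())
    assert [k for k, _ in lay.bands] == [
        "title", "mutations_primary", "backbone", "axis",
    ]


def test_secondary_mutations_add_a_distinct_band():
    lay = layout(_minimal_spec(mutations_secondary=[_mut(20)]))
    kinds = [k for k, _ in lay.bands]
    assert kinds.index("mutations_secondary") < kinds.index("mutations_primary")


def test_bands_are_disjoint_ordered_and_unique():
    spec = _minimal_spec(
        mutations_secondary=[_mut(20)], ptms=[PTMSite(5)],
        profile=_profile(), show_score=True, show_reference_sequence=True,
    )
    lay = layout(spec)
    kinds = [k for k, _ in lay.bands]
    assert len(kinds) == len(set(kinds))
    for (_, (lo1, hi1)), (_, (lo2, hi2)) in zip(lay.bands, lay.bands[1:]):
        assert hi1 > lo1 and hi2 > lo2
        assert lo1 == hi2  # stacked top-to-bottom with no overlap


def test_x_coordinate_is_affine_and_monotone_in_zoom_window():
    lay = layout(_minimal_spec(
        context=ProteinContext(length=1114, query_name="RET"),
        zoom=(600, 700),
    ))
    x636, x653 = lay.x(636), lay.x(653)
    assert 0.0 < x636 < x653 < 1.0
    # affine: equal residue steps are equal x steps
    assert lay.x(650) - lay.x(640) == pytest.approx(lay.x(660) - lay.x(650))


def test_zoom_window_validation():
    with pytest.raises(ValueError, match="zoom"):
        _minimal_spec(zoom=(50, 200))
    spec = _minimal_spec()
    with pytest.raises(ValueError, match="zoom"):
        zoom_view(spec, 70, 60)
    assert zoom_view(spec, 10, 60).zoom == (10, 60)
    assert spec.zoom is None  # original untouched


def test_score_without_profile_rejected():
    with pytest.raises(ValueError, match="profile"):
        _minimal_spec(show_score=True)


def test_letter_tracks_suppressed_on_wide_windows():
    spec = _minimal_spec(
        context=ProteinContext(length=1000, query_name="big"),
        profile=_profile(1000), show_reference_sequence=True,
    )
    wide = layout(spec)
    assert not wide.has("reference_sequence") and not wide.has("conservation_letters")
    narrow = layout(zoom_view(spec, 1, 150))
    assert narrow.has("reference_sequence") and narrow.has("conservation_letters")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_vector_output_is_byte_identical_across_runs(tmp_path, ret_fixture):
    spec = PlotSpec(
        context=ret_fixture.context,
        mutations_primary=ret_fixture.mutations,
        mutations_secondary=men2a_like_subset(ret_fixture.mutations),
        domains=ret_fixture.domains,
        ptms=ret_fixture.ptms,
    )
    a, b = tmp_path / "a.svg", tmp_path / "b.svg"
    render(spec, a)
    render(spec, b)
    assert a.read_bytes() == b.read_bytes()


def test_full_plot_draws_all_domains_and_markers(tmp_path, ret_fixture):
    spec = PlotSpec(
        context=ret_fixture.context,
        mutations_primary=ret_fixture.mutations,
        domains=ret_fixture.domains,
        ptms=ret_fixture.ptms,
    )
    out = tmp_path / "full.svg"
    render(spec, out)
    assert count_svg_ids(out, "domain-") == 4
    assert count_svg_ids(out, "mut-primary-") == len(ret_fixture.mutations)
    assert count_svg_ids(out, "ptm-") == len(ret_fixture.ptms)
    ids = list_svg_ids(out)
    for i in range(4):
        assert f"domainlabel-{i}" in ids


def test_zoom_drops_exactly_out_of_window_markers(tmp_path, ret_fixture):
    spec = PlotSpec(
        context=ret_fixture.context,
        mutations_primary=ret_fixture.mutations,
        domains=ret_fixture.domains,
        zoom=(600, 750),
    )
    out = tmp_path / "zoom.svg"
    render(spec, out)
    expected = sum(1 for m in ret_fixture.mutations if 600 <= m.position <= 750)
    assert count_svg_ids(out, "mut-primary-") == expected
    # Transmembrane (636-653) fully inside; Tyrosine Kinase straddles the
    # right edge and must still be (partially) drawn; SP/Cadherin are gone.
    ids = list_svg_ids(out)
    assert "domain-2" in ids and "domain-3" in ids
    assert "domain-0" not in ids and "domain-1" not in ids


def test_identity_zoom_renders_same_bytes_as_unzoomed(tmp_path):
    spec = _minimal_spec()
    a, b = tmp_path / "plain.svg", tmp_path / "zoomed.svg"
    render(spec, a)
    render(zoom_view(spec, 1, spec.context.length), b)
    assert a.read_bytes() == b.read_bytes()


def test_stacked_mutations_at_one_position_all_visible(tmp_path):
    spec = _minimal_spec(
        mutations_primary=[_mut(40, "C", a) for a in "RYW"] + [_mut(80)],
    )
    out = tmp_path / "stack.svg"
    render(spec, out)
    assert count_svg_ids(out, "mut-primary-") == 4
    assert count_svg_ids(out, "mutlabel-primary-") == 4


def test_two_track_figure_has_two_band_labels(tmp_path):
    spec = _minimal_spec(mutations_secondary=[_mut(20), _mut(21)])
    out = tmp_path / "two.svg"
    render(spec, out)
    ids = list_svg_ids(out)
    assert "band-primary" in ids and "band-secondary" in ids
    assert count_svg_ids(out, "mut-secondary-") == 2


def test_conservation_tracks_render_in_narrow_window(tmp_path):
    profile = _profile(100)
    spec = _minimal_spec(
        profile=profile, show_score=True, show_reference_sequence=True,
    )
    out = tmp_path / "cons.svg"
    render(spec, out)
    ids = list_svg_ids(out)
    assert "conservation-score" in ids
    assert count_svg_ids(out, "refseq-") == 100
    assert count_svg_ids(out, "consletter-") == 100


def test_gridlines_toggle(tmp_path):
    with_grid, without = tmp_path / "g.svg", tmp_path / "ng.svg"
    render(_minimal_spec(show_gridlines=True), with_grid)
    render(_minimal_spec(), without)
    assert "grid" in list_svg_ids(with_grid)
    assert "grid" not in list_svg_ids(without)


def test_pdf_and_png_outputs_exist(tmp_path):
    pdf_spec = _minimal_spec(output_format="pdf")
    png_spec = _minimal_spec(output_format="png")
    render(pdf_spec, tmp_path / "out.pdf")
    render(png_spec, tmp_path / "out.png")
    assert (tmp_path / "out.pdf").stat().st_size > 0
    assert (tmp_path / "out.png").read_bytes()[:4] == b"\x89PNG"


def test_unsupported_format_rejected():
    with pytest.raises(ValueError, match="unsupported output format"):
        _minimal_spec(output_format="tiff")


def test_long_domain_name_abbreviated_with_ellipsis(tmp_path):
    spec = _minimal_spec(
        domains=[DomainAnnotation("An Extremely Verbose Domain Name " * 4, 45, 55)],
    )
    out = tmp_path / "abbr.svg"
    render(spec, out)
    text = out.read_text()
    assert "\N{HORIZONTAL ELLIPSIS}" in text


# ---------------------------------------------------------------------------
# config file
# ---------------------------------------------------------------------------

def test_config_file_overrides_and_rejects_unknown_keys(tmp_path):
    path = tmp_path / "render.cfg"
    path.write_text(
        "primary_color = #000000  # black\n"
        "dpi = 72\n"
        "label_mutations = false\n"
        "domain_palette = #ff0000, #00ff00\n"
    )
    config = load_config(path)
    assert config.primary_color == "#000000"
    assert config.dpi == 72
    assert config.label_mutations is False
    assert config.domain_palette == ("#ff0000", "#00ff00")

    path.write_text("no_such_knob = 1\n")
    with pytest.raises(ValueError, match="unknown config key"):
        load_config(path)


def test_label_toggle_suppresses_labels(tmp_path):
    out = tmp_path / "nolabel.svg"
    render(_minimal_spec(), out, RenderConfig(label_mutations=False))
    assert count_svg_ids(out, "mutlabel-") == 0
    assert count_svg_ids(out, "mut-primary-") == 2
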