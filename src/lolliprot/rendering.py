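"""Multi-track protein schematic rendering.

Composes the lollipop figure: an optional second mutation track, the
primary mutation track, the protein backbone with domain boxes, PTM
marks, per-residue reference and conservation letters, a conservation
score bar track, and a residue-number axis -- over either the full
protein or a 1-based inclusive zoom window.

Output is written through matplotlib.  Vector output (SVG, the format
the tests parse) is deterministic: a fixed ``svg.hashsalt`` and stripped
date metadata make repeated renders of the same spec byte-identical.
Every semantic element carries a group id (``mut-primary-3``,
``domain-0``, ``ptm-2``, ...) so the SVG can be audited by parsing.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib as mpl
from matplotlib.figure import Figure
from matplotlib.ticker import MaxNLocator
from matplotlib.transforms import blended_transform_factory

from .conservation import ConservationProfile
from .io_formats import (
    DomainAnnotation,
    MutationRecord,
    ProteinContext,
    PTMSite,
)

logger = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("svg", "pdf", "png")

#: salt for matplotlib's SVG ids -- fixed so output is reproducible
_SVG_HASHSALT = "lolliprot"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Colours, sizes and toggles; all overridable from a flat config file."""

    primary_color: str = "#1f77b4"
    secondary_color: str = "#d62728"
    backbone_color: str = "#bbbbbb"
    ptm_color: str = "#6a3d9a"
    domain_palette: tuple[str, ...] = (
        "#8dd3c7", "#ffffb3", "#bebada", "#fb8072", "#80b1d3", "#fdb462",
    )
    dpi: int = 150
    fig_width: float = 12.0
    fig_height: Optional[float] = None  # None: derived from track count
    label_mutations: bool = True
    #: widest zoom window (in residues) at which per-residue letter
    #: tracks are still legible and therefore drawn
    letter_window_limit: int = 200


_CONFIG_PARSERS = {
    "primary_color": str,
    "secondary_color": str,
    "backbone_color": str,
    "ptm_color": str,
    "domain_palette": lambda v: tuple(c.strip() for c in v.split(",") if c.strip()),
    "dpi": int,
    "fig_width": float,
    "fig_height": float,
    "label_mutations": lambda v: v.strip().lower() in ("1", "true", "yes", "on"),
    "letter_window_limit": int,
}


def load_config(path: Union[str, Path]) -> RenderConfig:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    config = RenderConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        # '#' starts a comment only at line start or when followed by
        # whitespace, so hex colours like #1f77b4 survive
        line = raw.strip()
        if line.startswith("#"):
            continue
        line = re.split(r"\s+#(?=\s|$)", line, maxsplit=1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_PARSERS:
            raise ValueError(
                f"{path}, line {lineno}: unknown config key {key!r} "
                f"(known: {sorted(_CONFIG_PARSERS)})"
            )
        setattr(config, key, _CONFIG_PARSERS[key](value))
    return config


# ---------------------------------------------------------------------------
# plot specification
# ---------------------------------------------------------------------------

@dataclass
class PlotSpec:
    """Everything needed to render one figure."""

    context: ProteinContext
    mutations_primary: Sequence[MutationRecord]
    domains: Sequence[DomainAnnotation] = ()
    ptms: Sequence[PTMSite] = ()
    mutations_secondary: Optional[Sequence[MutationRecord]] = None
    profile: Optional[ConservationProfile] = None
    show_score: bool = False
    show_reference_sequence: bool = False
    show_gridlines: bool = False
    zoom: Optional[tuple[int, int]] = None
    track_labels: tuple[str, str] = ("All", "Set 2")
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.output_format not in SUPPORTED_FORMATS:
            raise ValueError(
                f"unsupported output format {self.output_format!r}; "
                f"choose one of {SUPPORTED_FORMATS}"
            )
        if self.zoom is not None:
            start, end = self.zoom
            if not (1 <= start <= end <= self.context.length):
                raise ValueError(
                    f"zoom window ({start}, {end}) invalid for protein of "
                    f"length {self.context.length}"
                )
        if self.show_score and self.profile is None:
            raise ValueError("show_score requires a conservation profile")
        if self.show_reference_sequence and self.profile is None:
            raise ValueError(
                "show_reference_sequence requires a conservation profile "
                "(letters come from the reference row)"
            )

    @property
    def window(self) -> tuple[int, int]:
        return self.zoom if self.zoom is not None else (1, self.context.length)


def zoom_view(spec: PlotSpec, start: int, end: int) -> PlotSpec:
    """Return a copy of ``spec`` restricted to [start, end] (inclusive).

    Inputs are not filtered here: clipping happens at render time so a
    domain box straddling the window edge is partially drawn.
    """
    return dataclasses.replace(spec, zoom=(start, end))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

#: vertical extent of each track kind, in layout units
_BAND_HEIGHTS = {
    "title": 0.9,
    "mutations_secondary": 2.4,
    "mutations_primary": 2.4,
    "backbone": 1.0,
    "ptm": 0.6,
    "reference_sequence": 0.6,
    "conservation_letters": 0.6,
    "conservation_score": 1.0,
    "axis": 0.8,
}


@dataclass(frozen=True)
class TrackLayout:
    """Disjoint vertical bands, top to bottom, plus the residue window."""

    bands: tuple[tuple[str, tuple[float, float]], ...]
    window: tuple[int, int]
    total_height: float

    def band(self, kind: str) -> tuple[float, float]:
        for k, b in self.bands:
            if k == kind:
                return b
        raise KeyError(f"track {kind!r} not present in this layout")

    def has(self, kind: str) -> bool:
        return any(k == kind for k, _ in self.bands)

    def x(self, position: Union[int, float]) -> float:
        """Horizontal coordinate of a residue as a fraction of the span.

        Affine in ``position``; residue ``start`` maps near 0 and
        ``end`` near 1 (each residue owns a unit-width cell).
        """
        start, end = self.window
        return (position - (start - 0.5)) / (end - start + 1)


def layout(spec: PlotSpec, config: Optional[RenderConfig] = None) -> TrackLayout:
    """Decide which tracks the figure has and stack their bands."""
    config = config or RenderConfig()
    start, end = spec.window
    span = end - start + 1
    letters_ok = span <= config.letter_window_limit

    kinds = ["title"]
    if spec.mutations_secondary is not None:
        kinds.append("mutations_secondary")
    kinds.append("mutations_primary")
    kinds.append("backbone")
    if spec.ptms:
        kinds.append("ptm")
    if spec.show_reference_sequence:
        if letters_ok:
            kinds.append("reference_sequence")
        else:
            logger.info(
                "reference-sequence track suppressed: window of %d residues "
                "exceeds the %d-residue legibility limit",
                span, config.letter_window_limit,
            )
    if spec.profile is not None:
        if letters_ok:
            kinds.append("conservation_letters")
        else:
            logger.info(
                "conservation-letter track suppressed: window of %d residues "
                "exceeds the %d-residue legibility limit",
                span, config.letter_window_limit,
            )
    if spec.show_score:
        kinds.append("conservation_score")
    kinds.append("axis")

    total = sum(_BAND_HEIGHTS[k] for k in kinds)
    bands = []
    top = total
    for kind in kinds:
        h = _BAND_HEIGHTS[kind]
        bands.append((kind, (top - h, top)))
        top -= h
    return TrackLayout(bands=tuple(bands), window=(start, end), total_height=total)


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------

def _conservation_color(score: float) -> str:
    # 3-bin scale: fully conserved / majority-conserved / weakly conserved
    if score >= 1.0:
        return "#1a9850"
    if score >= 0.5:
        return "#fd8d3c"
    return "#d73027"


def _tick_values(start: int, end: int) -> list[int]:
    ticks = MaxNLocator(nbins=10, integer=True).tick_values(start, end)
    values = sorted({int(t) for t in ticks if start <= t <= end})
    return values or [start]


def _in_window(position: int, window: tuple[int, int]) -> bool:
    return window[0] <= position <= window[1]


def _label_modes(positions: Sequence[float], min_sep: float) -> list[str]:
    """Deterministic label placement for horizontally sorted markers.

    Consecutive markers closer than ``min_sep`` form a collision group.
    Singletons go above the head; in groups of two or three the labels
    alternate above/below; denser groups are rotated 90 degrees.
    """
    modes: list[str] = []
    i = 0
    while i < len(positions):
        j = i + 1
        while j < len(positions) and positions[j] - positions[j - 1] < min_sep:
            j += 1
        group = j - i
        if group == 1:
            modes.append("above")
        elif group <= 3:
            modes.extend("above" if k % 2 == 0 else "below" for k in range(group))
        else:
            modes.extend(["rotated"] * group)
        i = j
    return modes


def _draw_mutation_track(
    ax,
    kind: str,
    mutations: Sequence[MutationRecord],
    band: tuple[float, float],
    color: str,
    track_label: str,
    window: tuple[int, int],
    config: RenderConfig,
) -> None:
    y0, y1 = band
    h = y1 - y0
    stem_base = y0 + 0.08 * h
    head_y0 = y0 + 0.45 * h
    head_step = 0.16 * h
    span = window[1] - window[0] + 1

    visible = [(i, m) for i, m in enumerate(mutations) if _in_window(m.position, window)]
    # stack order: repeated positions pile upwards in input order
    stack_depth: dict[int, int] = {}
    placed = []  # (position, head_y, label_text, running index)
    for idx, (orig_i, m) in enumerate(visible):
        depth = stack_depth.get(m.position, 0)
        stack_depth[m.position] = depth + 1
        head_y = head_y0 + depth * head_step
        (stem,) = ax.plot(
            [m.position, m.position], [stem_base, head_y],
            color=color, linewidth=0.9, solid_capstyle="butt", zorder=3,
        )
        stem.set_gid(f"stem-{kind}-{idx}")
        (head,) = ax.plot(
            [m.position], [head_y], marker="o", markersize=4.5,
            markerfacecolor=color, markeredgecolor="black",
            markeredgewidth=0.3, linestyle="none", zorder=4,
        )
        head.set_gid(f"mut-{kind}-{idx}")
        placed.append((m.position, head_y, m.label, idx))

    if config.label_mutations and placed:
        order = sorted(range(len(placed)), key=lambda k: (placed[k][0], placed[k][1]))
        xs = [placed[k][0] for k in order]
        modes = _label_modes(xs, min_sep=span * 0.03)
        for mode, k in zip(modes, order):
            pos, head_y, text, idx = placed[k]
            if mode == "above":
                kwargs = dict(y=head_y + 0.10 * h, ha="center", va="bottom", rotation=0)
            elif mode == "below":
                kwargs = dict(y=head_y - 0.10 * h, ha="center", va="top", rotation=0)
            else:  # rotated
                kwargs = dict(y=head_y + 0.08 * h, ha="center", va="bottom", rotation=90)
            label = ax.text(
                pos, kwargs.pop("y"), text, fontsize=5.5, color="black",
                zorder=5, clip_on=True, **kwargs,
            )
            label.set_gid(f"mutlabel-{kind}-{idx}")

    band_label = ax.text(
        0.004, (y0 + y1) / 2, track_label, fontsize=8, color=color,
        ha="left", va="center", fontweight="bold",
        transform=blended_transform_factory(ax.transAxes, ax.transData),
    )
    band_label.set_gid(f"band-{kind}")


def _abbreviate(name: str, max_chars: int) -> str:
    if len(name) <= max_chars:
        return name
    if max_chars < 2:
        return "\N{HORIZONTAL ELLIPSIS}"
    return name[: max_chars - 1] + "\N{HORIZONTAL ELLIPSIS}"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(
    spec: PlotSpec,
    path: Union[str, Path],
    config: Optional[RenderConfig] = None,
) -> None:
    """Render ``spec`` to ``path`` in spec.output_format (svg/pdf/png)."""
    config = config or RenderConfig()
    lay = layout(spec, config)
    wstart, wend = lay.window
    span = wend - wstart + 1
    H = lay.total_height

    fig_height = config.fig_height or max(2.5, 0.55 * H)
    with mpl.rc_context(
        {
            "svg.hashsalt": _SVG_HASHSALT,
            "svg.fonttype": "none",
            "font.family": "DejaVu Sans",
        }
    ):
        fig = Figure(figsize=(config.fig_width, fig_height))
        ax = fig.add_axes((0.05, 0.02, 0.92, 0.96))
        ax.set_xlim(wstart - 0.5, wend + 0.5)
        ax.set_ylim(0.0, H)
        ax.set_axis_off()

        ty0, ty1 = lay.band("title")
        title = ax.text(
            (wstart + wend) / 2, (ty0 + ty1) / 2, spec.context.query_name,
            ha="center", va="center", fontsize=13, fontweight="bold",
        )
        title.set_gid("title")

        if spec.show_gridlines:
            gy0 = lay.band("axis")[1]
            grid = ax.vlines(
                _tick_values(wstart, wend), gy0, lay.band("title")[0],
                colors="#dddddd", linewidth=0.6, zorder=0,
            )
            grid.set_gid("grid")

        # backbone and domain boxes
        by0, by1 = lay.band("backbone")
        bb_lo = max(0.5, wstart - 0.5)
        bb_hi = min(spec.context.length + 0.5, wend + 0.5)
        backbone = mpl.patches.Rectangle(
            (bb_lo, by0 + 0.35 * (by1 - by0)), bb_hi - bb_lo,
            0.30 * (by1 - by0), facecolor=config.backbone_color,
            edgecolor="black", linewidth=0.5, zorder=1,
        )
        backbone.set_gid("backbone")
        ax.add_patch(backbone)

        drawable_inches = config.fig_width * 0.92
        chars_per_residue = drawable_inches * 8.0 / span  # ~8 chars/inch at 9pt
        for i, d in enumerate(spec.domains):
            if d.end < wstart or d.start > wend:
                continue  # entirely outside the zoom window
            lo = max(d.start - 0.5, wstart - 0.5)
            hi = min(d.end + 0.5, wend + 0.5)
            box = mpl.patches.Rectangle(
                (lo, by0 + 0.12 * (by1 - by0)), hi - lo, 0.76 * (by1 - by0),
                facecolor=config.domain_palette[i % len(config.domain_palette)],
                edgecolor="black", linewidth=0.7, zorder=2,
            )
            box.set_gid(f"domain-{i}")
            ax.add_patch(box)
            max_chars = max(1, int((hi - lo) * chars_per_residue))
            dlabel = ax.text(
                (lo + hi) / 2, (by0 + by1) / 2, _abbreviate(d.name, max_chars),
                ha="center", va="center", fontsize=9, zorder=3, clip_on=True,
            )
            dlabel.set_gid(f"domainlabel-{i}")

        if spec.mutations_secondary is not None:
            _draw_mutation_track(
                ax, "secondary", spec.mutations_secondary,
                lay.band("mutations_secondary"), config.secondary_color,
                spec.track_labels[1], lay.window, config,
            )
        _draw_mutation_track(
            ax, "primary", spec.mutations_primary,
            lay.band("mutations_primary"), config.primary_color,
            spec.track_labels[0], lay.window, config,
        )

        if lay.has("ptm"):
            py0, py1 = lay.band("ptm")
            for i, site in enumerate(spec.ptms):
                if not _in_window(site.position, lay.window):
                    continue
                (mark,) = ax.plot(
                    [site.position], [(py0 + py1) / 2], marker="^",
                    markersize=5, markerfacecolor=config.ptm_color,
                    markeredgecolor="black", markeredgewidth=0.3,
                    linestyle="none", zorder=3,
                )
                mark.set_gid(f"ptm-{i}")

        profile = spec.profile
        if lay.has("reference_sequence") and profile is not None:
            ry = sum(lay.band("reference_sequence")) / 2
            for p in range(max(wstart, 1), min(wend, len(profile)) + 1):
                t = ax.text(
                    p, ry, profile.ref_letters[p - 1], ha="center",
                    va="center", fontsize=6, family="monospace",
                )
                t.set_gid(f"refseq-{p}")

        if lay.has("conservation_letters") and profile is not None:
            cy = sum(lay.band("conservation_letters")) / 2
            for p in range(max(wstart, 1), min(wend, len(profile)) + 1):
                s = float(profile.scores[p - 1])
                t = ax.text(
                    p, cy, profile.ref_letters[p - 1], ha="center",
                    va="center", fontsize=6, family="monospace",
                    color=_conservation_color(s),
                )
                t.set_gid(f"consletter-{p}")

        if lay.has("conservation_score") and profile is not None:
            sy0, sy1 = lay.band("conservation_score")
            lo_p = max(wstart, 1)
            hi_p = min(wend, len(profile))
            if lo_p <= hi_p:
                xs = list(range(lo_p, hi_p + 1))
                ys = [sy0 + 0.9 * (sy1 - sy0) * float(profile.scores[p - 1]) for p in xs]
                bars = ax.fill_between(
                    xs, sy0, ys, step="mid", color="#74add1",
                    edgecolor="none", zorder=2,
                )
                bars.set_gid("conservation-score")
                slabel = ax.text(
                    0.004, (sy0 + sy1) / 2, "s = n/t", fontsize=7,
                    ha="left", va="center", color="#45597e",
                    transform=blended_transform_factory(ax.transAxes, ax.transData),
                )
                slabel.set_gid("band-conservation-score")

        # residue-number axis
        ay0, ay1 = lay.band("axis")
        base_y = ay0 + 0.75 * (ay1 - ay0)
        axis_line = ax.hlines(base_y, wstart - 0.5, wend + 0.5, colors="black",
                              linewidth=0.8)
        axis_line.set_gid("axis-line")
        for tick in _tick_values(wstart, wend):
            tl = ax.vlines(tick, base_y - 0.12 * (ay1 - ay0), base_y,
                           colors="black", linewidth=0.8)
            tl.set_gid(f"tickmark-{tick}")
            tt = ax.text(tick, base_y - 0.2 * (ay1 - ay0), str(tick),
                         ha="center", va="top", fontsize=7)
            tt.set_gid(f"ticklabel-{tick}")

        fmt = spec.output_format
        if fmt == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        elif fmt == "pdf":
            fig.savefig(path, format="pdf",
                        metadata={"CreationDate": None, "Producer": None})
        else:
            fig.savefig(path, format="png", dpi=config.dpi)


# ---------------------------------------------------------------------------
# SVG audit helper (used by the test-suite and acceptance checks)
# ---------------------------------------------------------------------------

def list_svg_ids(path: Union[str, Path]) -> list[str]:
    """All element ids in an SVG file, in document order."""
    root = ET.parse(str(path)).getroot()
    return [el.attrib["id"] for el in root.iter() if "id" in el.attrib]


def count_svg_ids(path: Union[str, Path], prefix: str) -> int:
    """Number of SVG elements whose id starts with ``prefix``."""
    return sum(1 for i in list_svg_ids(path) if i.startswith(prefix))
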