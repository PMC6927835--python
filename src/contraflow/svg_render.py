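"""Static SVG rendering of chord layouts.

Semantics mirrored from the diagram design: method arcs are shaded on a
single-hue sequential ramp so darker always means more effective; non-use
is neutral gray; every ribbon is filled with its ORIGIN arc's color so the
direction of a flow is readable at a glance; a dashed vertical divider
separates baseline (left) from follow-up (right); and each ribbon carries a
declarative hover annotation (an SVG ``<title>``) stating origin,
destination, and weighted count — no scripting.

Reason diagrams reuse the same machinery: methods on the left, reasons on
the right with the "in need" class in dark shades and the rest light.

Output is deterministic: identical inputs give byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping
from xml.etree import ElementTree as ET

from .chord_layout import (
    ArcSpan,
    ChordLayout,
    LayoutError,
    compute_layout,
    polar_to_xy,
    ribbon_path,
)
from .codes import NONUSE_LABEL, PREGNANT_LABEL, CodeMap
from .transitions import ReasonFlowMatrix

# Canvas constants: fixed 800x800 viewBox, circle radius 320.
CANVAS = 800
CENTER = (400.0, 400.0)
RADIUS = 320.0
ARC_THICKNESS = 18.0
LABEL_RADIUS = 340.0

_DARK_METHOD = (8, 48, 107)  # deep blue: most effective
_LIGHT_METHOD = (198, 219, 239)  # pale blue: least effective
_GRAY = "#999999"
_DARK_NEED = (8, 69, 148)
_LIGHT_NEED = (158, 202, 225)


class RenderError(ValueError):
    pass


def _lerp_hex(a: tuple[int, int, int], b: tuple[int, int, int], u: float) -> str:
    rgb = tuple(round(a[k] + (b[k] - a[k]) * u) for k in range(3))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def luminance(color: str) -> float:
    """Relative luminance of a #rrggbb color (0 dark .. 1 light)."""
    r, g, b = (int(color[i : i + 2], 16) / 255 for i in (1, 3, 5))
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


@dataclass(frozen=True)
class Palette:
    """Label -> fill color, dark = high efficacy / in-need."""

    colors: Mapping[str, str] = field(default_factory=dict)

    def color(self, label: str) -> str:
        try:
            return self.colors[label]
        except KeyError:
            raise RenderError(f"palette has no color for {label!r}") from None

    def covers(self, labels) -> bool:
        return all(label in self.colors for label in labels)


def method_palette(codes: CodeMap) -> Palette:
    """Sequential dark-to-light ramp over the effectiveness order.

    Linear interpolation in RGB between a dark and a light anchor keeps the
    luminance strictly monotone in the efficacy rank.  Non-use (and the
    optional pregnancy destination) fall outside the ramp in neutral gray.
    """
    order = codes.effectiveness_order
    n = len(order)
    colors = {
        m: _lerp_hex(_DARK_METHOD, _LIGHT_METHOD, i / max(n - 1, 1))
        for i, m in enumerate(order)
    }
    colors[NONUSE_LABEL] = _GRAY
    colors[PREGNANT_LABEL] = "#bbbbbb"
    return Palette(colors)


def reason_palette(codes: CodeMap, methods: Palette | None = None) -> Palette:
    """Method ramp plus reason shades: dark blues for in-need, light otherwise."""
    base = dict((methods or method_palette(codes)).colors)
    in_need = sorted(r for r, k in codes.need_map.items() if k == "in_need")
    not_in_need = sorted(r for r, k in codes.need_map.items() if k == "not_in_need")
    for i, r in enumerate(in_need):
        base[r] = _lerp_hex(_DARK_NEED, tuple(c - 40 for c in _LIGHT_NEED), i / max(len(in_need) - 1, 1))
    for i, r in enumerate(not_in_need):
        base[r] = _lerp_hex(tuple(min(c + 40, 255) for c in _LIGHT_NEED), (225, 238, 248), i / max(len(not_in_need) - 1, 1))
    return Palette(base)


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _annulus_sector_path(arc: ArcSpan) -> str:
    """Closed path for an arc's annulus sector between RADIUS and RADIUS+thickness."""
    r0, r1 = RADIUS, RADIUS + ARC_THICKNESS
    a = polar_to_xy(arc.theta_start, r0, CENTER)
    b = polar_to_xy(arc.theta_end, r0, CENTER)
    c = polar_to_xy(arc.theta_end, r1, CENTER)
    d = polar_to_xy(arc.theta_start, r1, CENTER)
    large = 1 if arc.width > math.pi else 0
    return " ".join(
        [
            f"M {_fmt(a[0])} {_fmt(a[1])}",
            f"A {_fmt(r0)} {_fmt(r0)} 0 {large} 1 {_fmt(b[0])} {_fmt(b[1])}",
            f"L {_fmt(c[0])} {_fmt(c[1])}",
            f"A {_fmt(r1)} {_fmt(r1)} 0 {large} 0 {_fmt(d[0])} {_fmt(d[1])}",
            "Z",
        ]
    )


def _format_weight(value: float) -> str:
    return f"{value:g}"


def render(
    layout: ChordLayout,
    palette: Palette,
    title: str | None = None,
    ribbon_opacity: float = 0.72,
) -> str:
    """Render a chord layout to a standalone SVG document (as a string).

    Every arc becomes a filled annulus sector with a text label and its
    weighted total; every ribbon a filled path colored by its origin with a
    hover ``<title>``; the dashed vertical divider marks the baseline /
    follow-up split.
    """
    if not layout.arcs:
        raise RenderError("empty diagram: layout has no arcs")
    for arc in layout.arcs:
        palette.color(arc.label)  # raises early on a missing color

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "viewBox": f"0 0 {CANVAS} {CANVAS}",
            "width": str(CANVAS),
            "height": str(CANVAS),
        },
    )
    if title:
        t = ET.SubElement(svg, "title")
        t.text = title

    ribbons_g = ET.SubElement(svg, "g", {"class": "ribbons"})
    for r in layout.ribbons:
        path = ET.SubElement(
            ribbons_g,
            "path",
            {
                "d": ribbon_path(r, RADIUS, CENTER),
                "fill": palette.color(r.origin_label),
                "fill-opacity": f"{ribbon_opacity:g}",
                "stroke": "none",
                "data-direction": r.direction,
            },
        )
        hover = ET.SubElement(path, "title")
        hover.text = (
            f"{r.origin_label} → {r.destination_label}: {_format_weight(r.value)}"
        )

    # Zero-width arcs are emitted as degenerate paths so both sides always
    # carry the full label set in display order.
    arcs_g = ET.SubElement(svg, "g", {"class": "arcs"})
    for arc in layout.arcs:
        ET.SubElement(
            arcs_g,
            "path",
            {
                "d": _annulus_sector_path(arc),
                "fill": palette.color(arc.label),
                "stroke": "#ffffff",
                "stroke-width": "0.5",
                "data-side": arc.side,
                "data-theta-start": f"{arc.theta_start:.9f}",
                "data-theta-end": f"{arc.theta_end:.9f}",
            },
        )

    labels_g = ET.SubElement(svg, "g", {"class": "labels", "font-size": "13", "font-family": "sans-serif"})
    for arc in layout.arcs:
        mid = (arc.theta_start + arc.theta_end) / 2
        x, y = polar_to_xy(mid, LABEL_RADIUS, CENTER)
        anchor = "start" if arc.side == "right" else "end"
        text = ET.SubElement(
            labels_g,
            "text",
            {"x": _fmt(x), "y": _fmt(y), "text-anchor": anchor, "dominant-baseline": "middle"},
        )
        text.text = f"{arc.label} ({_format_weight(arc.value)})"

    # Dashed vertical divider between baseline (left) and follow-up (right).
    ET.SubElement(
        svg,
        "line",
        {
            "x1": _fmt(CENTER[0]),
            "y1": _fmt(CENTER[1] - RADIUS - ARC_THICKNESS),
            "x2": _fmt(CENTER[0]),
            "y2": _fmt(CENTER[1] + RADIUS + ARC_THICKNESS),
            "stroke": "#444444",
            "stroke-width": "1.5",
            "stroke-dasharray": "8 6",
            "class": "divider",
        },
    )

    return ET.tostring(svg, encoding="unicode") + "\n"


def render_reason_diagram(
    matrix: ReasonFlowMatrix,
    codes: CodeMap,
    palette: Palette | None = None,
    gap: float = 0.03,
    title: str | None = None,
) -> str:
    """Render a reasons-for-discontinuation diagram for one population.

    Left side: origin methods in effectiveness order and shading.  Right
    side: reason arcs, in-need class first in dark shades, then the rest in
    light shades.  Raises on an all-zero matrix.
    """
    if matrix.grand_total <= 0:
        raise LayoutError("empty diagram: reason matrix grand total is zero")
    layout = compute_layout(matrix, gap=gap)
    pal = palette or reason_palette(codes)
    default_title = f"Reasons for discontinuation ({matrix.population})"
    return render(layout, pal, title=title or default_title)


def write_svg(document: str, path: str | Path) -> None:
    Path(path).write_text(document)


def write_html_wrapper(document: str, path: str | Path, title: str = "Chord diagram") -> None:
    """Convenience HTML page embedding the SVG inline."""
    html = (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{title}</title></head>\n<body>\n{document}</body></html>\n"
    )
    Path(path).write_text(html)


__all__ = [
    "ARC_THICKNESS",
    "CANVAS",
    "CENTER",
    "LABEL_RADIUS",
    "Palette",
    "RADIUS",
    "RenderError",
    "luminance",
    "method_palette",
    "reason_palette",
    "render",
    "render_reason_diagram",
    "write_html_wrapper",
    "write_svg",
]
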