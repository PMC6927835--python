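"""Bipartite chord-diagram geometry.

The diagram is a circle split in half by a vertical divider: origin groups
(baseline) occupy the left half, destination groups (follow-up) the right.
Because every woman appears on both sides, the two halves represent equal
totals and each half's usable angle is divided among its groups in
proportion to their weighted marginals.  Each flow becomes a ribbon joining
a sub-arc of its origin group to a sub-arc of its destination group, with
width proportional to the flow's weight.

Angular frame: angles are measured in radians clockwise from 12 o'clock.
The right half is (0, pi) running down the right side; the left half is
(pi, 2*pi) running up the left side.  On both sides groups are ordered
top-to-bottom by typical-use effectiveness, most effective at the top and
non-use at the bottom, so a ribbon that "arcs downward" always means a move
to a less effective method or to non-use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .transitions import FlowMatrix

Side = Literal["left", "right"]
Direction = Literal["up", "down", "flat"]

DEFAULT_GAP = 0.03  # radians between adjacent groups and at the divider ends


class LayoutError(ValueError):
    """The matrix cannot be laid out (empty, or gaps exceed a half-circle)."""


@dataclass(frozen=True)
class ArcSpan:
    """Angular span of one group on one side of the circle."""

    label: str
    side: Side
    theta_start: float
    theta_end: float
    value: float

    @property
    def width(self) -> float:
        return self.theta_end - self.theta_start


@dataclass(frozen=True)
class Ribbon:
    """One flow: a sub-arc on each side plus its vertical tendency."""

    origin_label: str
    destination_label: str
    value: float
    origin_sub_arc: tuple[float, float]
    destination_sub_arc: tuple[float, float]
    direction: Direction


@dataclass(frozen=True)
class ChordLayout:
    arcs: tuple[ArcSpan, ...]
    ribbons: tuple[Ribbon, ...]
    gap: float
    radius: float = 1.0

    def arcs_on(self, side: Side) -> list[ArcSpan]:
        return [a for a in self.arcs if a.side == side]

    def arc(self, side: Side, label: str) -> ArcSpan:
        for a in self.arcs:
            if a.side == side and a.label == label:
                return a
        raise KeyError(f"no {side} arc labelled {label!r}")

    def to_dict(self) -> dict:
        return {
            "gap": self.gap,
            "radius": self.radius,
            "arcs": [
                {
                    "label": a.label,
                    "side": a.side,
                    "theta_start": a.theta_start,
                    "theta_end": a.theta_end,
                    "value": a.value,
                }
                for a in self.arcs
            ],
            "ribbons": [
                {
                    "origin_label": r.origin_label,
                    "destination_label": r.destination_label,
                    "value": r.value,
                    "origin_sub_arc": list(r.origin_sub_arc),
                    "destination_sub_arc": list(r.destination_sub_arc),
                    "direction": r.direction,
                }
                for r in self.ribbons
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ChordLayout":
        return cls(
            arcs=tuple(ArcSpan(**a) for a in payload["arcs"]),
            ribbons=tuple(
                Ribbon(
                    origin_label=r["origin_label"],
                    destination_label=r["destination_label"],
                    value=r["value"],
                    origin_sub_arc=tuple(r["origin_sub_arc"]),
                    destination_sub_arc=tuple(r["destination_sub_arc"]),
                    direction=r["direction"],
                )
                for r in payload["ribbons"]
            ),
            gap=payload["gap"],
            radius=payload.get("radius", 1.0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChordLayout":
        return cls.from_dict(json.loads(Path(path).read_text()))


def polar_to_xy(theta: float, radius: float, center: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
    """Point at angle ``theta`` (clockwise from 12 o'clock) and given radius."""
    cx, cy = center
    return cx + radius * math.sin(theta), cy - radius * math.cos(theta)


def xy_to_theta(x: float, y: float, center: tuple[float, float] = (0.0, 0.0)) -> float:
    """Inverse of :func:`polar_to_xy`; result in [0, 2*pi)."""
    cx, cy = center
    return math.atan2(x - cx, cy - y) % (2 * math.pi)


def _side_spans(
    values: Sequence[float], side: Side, gap: float
) -> list[tuple[float, float]]:
    """Partition one half-circle among groups, top to bottom, gaps between.

    ``values`` are the group marginals in top-to-bottom display order.
    On the right, top-to-bottom means increasing theta from just after 0;
    on the left it means decreasing theta from just before 2*pi.
    """
    n = len(values)
    usable = math.pi - (n + 1) * gap
    if usable <= 0:
        raise LayoutError(f"gap {gap} too large for {n} groups per side")
    total = float(sum(values))
    widths = [usable * v / total for v in values]
    spans: list[tuple[float, float]] = []
    if side == "right":
        theta = gap
        for w in widths:
            spans.append((theta, theta + w))
            theta += w + gap
    else:
        theta = 2 * math.pi - gap
        for w in widths:
            spans.append((theta - w, theta))
            theta -= w + gap
    return spans


def compute_layout(
    matrix: FlowMatrix,
    gap: float = DEFAULT_GAP,
    rank: Mapping[str, int] | None = None,
    radius: float = 1.0,
) -> ChordLayout:
    """Lay out a flow matrix on the bipartite circle.

    Origins take the left half in the matrix's row order (assumed to be the
    effectiveness display order, most effective first); destinations take
    the right half in column order.  Group widths are proportional to row
    (resp. column) marginals, so they are invariant to any global rescaling
    of the matrix.  Zero-marginal groups keep a zero-width arc so both
    sides always display the full label set.

    Within each origin arc, sub-arcs are ordered by destination display
    order; within each destination arc, by origin display order.  Ribbon
    direction compares the endpoints' ranks (row/column position by
    default, or the supplied ``rank``): "up" toward a more effective
    destination, "down" toward less effective or non-use, "flat" for
    continuation.
    """
    total = matrix.grand_total
    if total <= 0:
        raise LayoutError("empty diagram: flow matrix grand total is zero")

    origins, destinations = matrix.origin_labels, matrix.destination_labels
    row = matrix.cells.sum(axis=1)
    col = matrix.cells.sum(axis=0)
    left = _side_spans(row, "left", gap)
    right = _side_spans(col, "right", gap)

    arcs = tuple(
        [
            ArcSpan(label, "left", s, e, float(v))
            for label, (s, e), v in zip(origins, left, row)
        ]
        + [
            ArcSpan(label, "right", s, e, float(v))
            for label, (s, e), v in zip(destinations, right, col)
        ]
    )

    if rank is None:
        # Display position doubles as the effectiveness rank; when a label
        # appears on both sides (same method at baseline and follow-up) the
        # shared ranking makes "flat" well defined.
        order: list[str] = list(origins)
        for d in destinations:
            if d not in order:
                order.append(d)
        rank = {label: i for i, label in enumerate(order)}

    # Sub-arc cursors advance top-to-bottom inside each parent arc: toward
    # increasing theta on the right, decreasing on the left.
    ribbons: list[Ribbon] = []
    left_cursor = {label: span[1] for label, span in zip(origins, left)}
    right_cursor = {label: span[0] for label, span in zip(destinations, right)}

    def take_left(label: str, width: float) -> tuple[float, float]:
        hi = left_cursor[label]
        left_cursor[label] = hi - width
        return (hi - width, hi)

    def take_right(label: str, width: float) -> tuple[float, float]:
        lo = right_cursor[label]
        right_cursor[label] = lo + width
        return (lo, lo + width)

    # Origin sub-arcs in destination display order; the destination-side
    # sub-arc of the same cell must land in origin display order, which the
    # column-major second pass below guarantees.
    origin_sub: dict[tuple[int, int], tuple[float, float]] = {}
    for i, (o_label, (s, e)) in enumerate(zip(origins, left)):
        arc_width = e - s
        row_total = row[i]
        for j in range(len(destinations)):
            v = matrix.cells[i, j]
            w = arc_width * v / row_total if row_total > 0 else 0.0
            origin_sub[(i, j)] = take_left(o_label, w)

    for j, (d_label, (s, e)) in enumerate(zip(destinations, right)):
        arc_width = e - s
        col_total = col[j]
        for i in range(len(origins)):
            v = matrix.cells[i, j]
            if v == 0:
                continue
            w = arc_width * v / col_total if col_total > 0 else 0.0
            o_label = origins[i]
            ro, rd = rank.get(o_label), rank.get(d_label)
            if ro is None or rd is None or rd > ro:
                direction: Direction = "down"
            elif rd < ro:
                direction = "up"
            else:
                direction = "flat"
            ribbons.append(
                Ribbon(
                    origin_label=o_label,
                    destination_label=d_label,
                    value=float(v),
                    origin_sub_arc=origin_sub[(i, j)],
                    destination_sub_arc=take_right(d_label, w),
                    direction=direction,
                )
            )

    return ChordLayout(arcs=arcs, ribbons=tuple(ribbons), gap=gap, radius=radius)


def ribbon_path(
    ribbon: Ribbon,
    radius: float,
    center: tuple[float, float] = (0.0, 0.0),
) -> str:
    """SVG path for a ribbon: two circle arcs joined by quadratic curves.

    The path runs along the origin sub-arc on the circle, curves through the
    circle center (the Bezier control point) to the destination sub-arc,
    runs along it, and curves back.  For sub-arcs narrower than pi the path
    does not self-intersect.
    """
    (o0, o1), (d0, d1) = ribbon.origin_sub_arc, ribbon.destination_sub_arc
    p = [polar_to_xy(t, radius, center) for t in (o0, o1, d0, d1)]

    def arc_to(t_from: float, t_to: float, end: tuple[float, float]) -> str:
        sweep = 1 if t_to > t_from else 0  # clockwise theta grows => sweep 1
        large = 1 if abs(t_to - t_from) > math.pi else 0
        return f"A {radius:.6f} {radius:.6f} 0 {large} {sweep} {end[0]:.6f} {end[1]:.6f}"

    cx, cy = center
    return " ".join(
        [
            f"M {p[0][0]:.6f} {p[0][1]:.6f}",
            arc_to(o0, o1, p[1]),
            f"Q {cx:.6f} {cy:.6f} {p[2][0]:.6f} {p[2][1]:.6f}",
            arc_to(d0, d1, p[3]),
            f"Q {cx:.6f} {cy:.6f} {p[0][0]:.6f} {p[0][1]:.6f}",
            "Z",
        ]
    )


def ribbon_polygon(
    ribbon: Ribbon,
    radius: float,
    center: tuple[float, float] = (0.0, 0.0),
    samples: int = 64,
) -> np.ndarray:
    """Sample the ribbon outline as a closed polygon (for area checks)."""
    (o0, o1), (d0, d1) = ribbon.origin_sub_arc, ribbon.destination_sub_arc
    pts: list[tuple[float, float]] = []
    for t in np.linspace(o0, o1, samples):
        pts.append(polar_to_xy(float(t), radius, center))
    pts.extend(_quad_bezier(polar_to_xy(o1, radius, center), center, polar_to_xy(d0, radius, center), samples))
    for t in np.linspace(d0, d1, samples):
        pts.append(polar_to_xy(float(t), radius, center))
    pts.extend(_quad_bezier(polar_to_xy(d1, radius, center), center, polar_to_xy(o0, radius, center), samples))
    return np.asarray(pts)


def _quad_bezier(p0, c, p1, samples: int) -> list[tuple[float, float]]:
    out = []
    for u in np.linspace(0.0, 1.0, samples):
        x = (1 - u) ** 2 * p0[0] + 2 * (1 - u) * u * c[0] + u**2 * p1[0]
        y = (1 - u) ** 2 * p0[1] + 2 * (1 - u) * u * c[1] + u**2 * p1[1]
        out.append((float(x), float(y)))
    return out


def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polygon (absolute value)."""
    x, y = points[:, 0], points[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


__all__ = [
    "DEFAULT_GAP",
    "ArcSpan",
    "ChordLayout",
    "Direction",
    "LayoutError",
    "Ribbon",
    "Side",
    "compute_layout",
    "polar_to_xy",
    "polygon_area",
    "ribbon_path",
    "ribbon_polygon",
    "xy_to_theta",
]
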