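"""Bipartite layout geometry: angle budgets, sub-arc partitions, ribbons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contraflow.chord_layout import (
    ChordLayout,
    LayoutError,
    compute_layout,
    polar_to_xy,
    polygon_area,
    ribbon_path,
    ribbon_polygon,
    xy_to_theta,
)
from contraflow.transitions import FlowMatrix


def matrix(cells, origins=None, destinations=None):
    cells = np.asarray(cells, dtype=float)
    n, m = cells.shape
    return FlowMatrix(
        origin_labels=origins or [f"o{i}" for i in range(n)],
        destination_labels=destinations or [f"d{j}" for j in range(m)],
        cells=cells,
    )


def side_budget(layout: ChordLayout, side: str) -> float:
    arcs = layout.arcs_on(side)
    return sum(a.width for a in arcs) + (len(arcs) + 1) * layout.gap


class TestComputeLayout:
    def test_single_cell_fills_both_halves(self):
        layout = compute_layout(matrix([[5.0]]), gap=0.0)
        (left,) = layout.arcs_on("left")
        (right,) = layout.arcs_on("right")
        assert left.width == pytest.approx(math.pi)
        assert right.width == pytest.approx(math.pi)

    def test_widths_proportional_to_marginals(self):
        layout = compute_layout(matrix([[1.0], [3.0]]), gap=0.0)
        a, b = layout.arcs_on("left")
        assert a.width == pytest.approx(math.pi / 4)
        assert b.width == pytest.approx(3 * math.pi / 4)

    def test_tutorial_injections_arc_fraction(self, tut_table):
        """The injections origin arc takes 439/1207 of the usable left angle."""
        gap = 0.03
        layout = compute_layout(tut_table, gap=gap)
        usable = math.pi - (len(tut_table.origin_labels) + 1) * gap
        arc = layout.arc("left", "injections")
        assert arc.width == pytest.approx((439 / 1207) * usable)

    def test_empty_matrix_raises(self):
        with pytest.raises(LayoutError, match="empty"):
            compute_layout(matrix([[0.0]]))

    def test_oversized_gap_raises(self):
        with pytest.raises(LayoutError, match="gap"):
            compute_layout(matrix([[1.0]]), gap=2.0)

    def test_left_arcs_in_left_half_right_in_right(self, tut_table):
        layout = compute_layout(tut_table)
        for arc in layout.arcs_on("left"):
            assert math.pi <= arc.theta_start <= arc.theta_end <= 2 * math.pi
        for arc in layout.arcs_on("right"):
            assert 0 <= arc.theta_start <= arc.theta_end <= math.pi

    def test_effectiveness_order_top_to_bottom(self, tut_table):
        # top of the left half is theta ~ 2*pi, top of the right ~ 0:
        # rows are ordered most effective first, so theta must decrease on
        # the left and increase on the right along the label order
        layout = compute_layout(tut_table)
        left = layout.arcs_on("left")
        assert [a.label for a in left] == tut_table.origin_labels
        assert all(x.theta_start > y.theta_end - 1e-12 for x, y in zip(left, left[1:]))
        right = layout.arcs_on("right")
        assert [a.label for a in right] == tut_table.destination_labels
        assert all(x.theta_end < y.theta_start + 1e-12 for x, y in zip(right, right[1:]))

    def test_zero_marginal_groups_keep_zero_width_arcs(self):
        layout = compute_layout(matrix([[1.0, 0.0], [0.0, 0.0]]))
        assert layout.arc("left", "o1").width == 0
        assert layout.arc("right", "d1").width == 0
        assert len(layout.arcs) == 4

    def test_ribbon_directions(self):
        # shared label set: o0/d0 most effective, o2/d2 least ("non-use"-like)
        labels = ["a", "b", "c"]
        cells = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [0.0, 0.0, 1.0]]
        layout = compute_layout(matrix(cells, origins=labels, destinations=labels))
        directions = {
            (r.origin_label, r.destination_label): r.direction for r in layout.ribbons
        }
        assert directions[("a", "a")] == "flat"
        assert directions[("a", "b")] == "down"
        assert directions[("b", "a")] == "up"
        assert directions[("b", "c")] == "down"

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0, 100), min_size=3, max_size=3),
            min_size=2,
            max_size=5,
        ),
        st.floats(0.0, 0.1),
    )
    def test_angle_conservation_on_random_matrices(self, cells, gap):
        """Per side: arc widths plus gaps fill exactly half the circle."""
        cells = np.asarray(cells)
        if cells.sum() <= 0:
            return
        layout = compute_layout(matrix(cells), gap=gap)
        assert side_budget(layout, "left") == pytest.approx(math.pi, abs=1e-9)
        assert side_budget(layout, "right") == pytest.approx(math.pi, abs=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0, 50), min_size=3, max_size=3),
            min_size=2,
            max_size=4,
        )
    )
    def test_sub_arc_partition_is_exact(self, cells):
        cells = np.asarray(cells)
        if cells.sum() <= 0:
            return
        layout = compute_layout(matrix(cells))
        for side, attr in (("left", "origin_sub_arc"), ("right", "destination_sub_arc")):
            key = "origin_label" if side == "left" else "destination_label"
            for arc in layout.arcs_on(side):
                subs = [
                    getattr(r, attr)
                    for r in layout.ribbons
                    if getattr(r, key) == arc.label
                ]
                total = sum(hi - lo for lo, hi in subs)
                covered = arc.width if arc.value else 0.0
                # zero-value flows are dropped from ribbons, so compare
                # against the weighted share actually drawn
                drawn = sum(
                    r.value
                    for r in layout.ribbons
                    if getattr(r, key) == arc.label
                )
                assert total == pytest.approx(
                    arc.width * (drawn / arc.value) if arc.value else 0.0, abs=1e-9
                )
                for lo, hi in subs:
                    assert arc.theta_start - 1e-9 <= lo <= hi <= arc.theta_end + 1e-9

    def test_scale_invariance(self, tut_table):
        layout1 = compute_layout(tut_table)
        scaled = FlowMatrix(
            tut_table.origin_labels,
            tut_table.destination_labels,
            tut_table.cells * 137.5,
        )
        layout2 = compute_layout(scaled)
        for a, b in zip(layout1.arcs, layout2.arcs):
            assert a.theta_start == pytest.approx(b.theta_start, abs=1e-12)
            assert a.theta_end == pytest.approx(b.theta_end, abs=1e-12)

    def test_layout_json_round_trip(self, tmp_path, tut_table):
        layout = compute_layout(tut_table)
        path = tmp_path / "layout.json"
        layout.to_json(path)
        back = ChordLayout.from_json(path)
        assert back == layout


class TestRibbonGeometry:
    def test_polar_round_trip(self):
        for theta in np.linspace(0.01, 2 * math.pi - 0.01, 17):
            x, y = polar_to_xy(theta, 1.0)
            assert xy_to_theta(x, y) == pytest.approx(theta, abs=1e-12)

    def test_zero_width_ribbon_has_zero_area(self):
        layout = compute_layout(matrix([[1.0]]), gap=0.2)
        (r,) = layout.ribbons
        from contraflow.chord_layout import Ribbon

        degenerate = Ribbon(
            r.origin_label,
            r.destination_label,
            0.0,
            (r.origin_sub_arc[0], r.origin_sub_arc[0]),
            (r.destination_sub_arc[0], r.destination_sub_arc[0]),
            r.direction,
        )
        assert polygon_area(ribbon_polygon(degenerate, 1.0)) == pytest.approx(0, abs=1e-12)

    def test_symmetric_ribbon_is_mirror_symmetric(self):
        """Equal sub-arc widths at horizontally mirrored angles give a path
        symmetric about the horizontal axis through the center."""
        from contraflow.chord_layout import Ribbon

        w = 0.4
        # right-side sub-arc straddling 3 o'clock, left-side straddling 9
        r = Ribbon("o", "d", 1.0, (3 * math.pi / 2 - w / 2, 3 * math.pi / 2 + w / 2),
                   (math.pi / 2 - w / 2, math.pi / 2 + w / 2), "flat")
        poly = ribbon_polygon(r, 1.0, samples=200)
        flipped = poly.copy()
        flipped[:, 1] *= -1
        # same point set up to ordering: compare sorted rows
        a = np.array(sorted(map(tuple, np.round(poly, 9))))
        b = np.array(sorted(map(tuple, np.round(flipped, 9))))
        assert np.allclose(a, b, atol=1e-6)

    def test_area_monotone_in_ribbon_value(self):
        """Widening a flow (all else fixed) grows the enclosed area."""
        areas = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            m = matrix([[frac, 1 - frac]])
            layout = compute_layout(m, gap=0.0)
            ribbon = next(r for r in layout.ribbons if r.destination_label == "d0")
            areas.append(polygon_area(ribbon_polygon(ribbon, 1.0)))
        assert all(x < y for x, y in zip(areas, areas[1:]))

    def test_path_string_is_closed_and_parsable(self):
        layout = compute_layout(matrix([[2.0, 1.0], [1.0, 1.0]]))
        for r in layout.ribbons:
            d = ribbon_path(r, 320.0, (400.0, 400.0))
            assert d.startswith("M ") and d.endswith("Z")
            assert d.count("A ") == 2 and d.count("Q ") == 2
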