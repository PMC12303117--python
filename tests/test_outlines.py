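import numpy as np
import pytest

from wingmorph.outlines import (
    centroid_size,
    is_self_intersecting,
    orient_standard,
    polygon_area,
    read_outline,
    resample_equal_arclength,
    signed_area,
    wing_span,
    write_outline_csv,
)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
RECT41 = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 1.0], [0.0, 1.0]])


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "rect.csv"
        write_outline_csv(RECT41, path)
        assert np.allclose(read_outline(path), RECT41)

    def test_csv_rectangle(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("0,0\n4,0\n4,1\n0,1\n")
        v = read_outline(path)
        assert v.shape == (4, 2)
        assert polygon_area(v) == 4.0

    def test_tps_roundtrip(self, tmp_path, wing_outline):
        from wingmorph.outlines import write_outline_tps

        path = tmp_path / "wing.tps"
        write_outline_tps(wing_outline, path)
        assert np.array_equal(read_outline(path, "tps"), wing_outline)

    def test_tps_matches_csv(self, tmp_path):
        tps = tmp_path / "o.tps"
        tps.write_text("LM=0\nOUTLINES=1\nPOINTS=4\n0 0\n4 0\n4 1\n0 1\nID=1\n")
        csv = tmp_path / "o.csv"
        csv.write_text("0,0\n4,0\n4,1\n0,1\n")
        assert np.array_equal(read_outline(tps, "tps"), read_outline(csv))

    def test_too_few_points_rejected(self, tmp_path):
        path = tmp_path / "two.csv"
        path.write_text("0,0\n1,1\n")
        with pytest.raises(ValueError, match="3 points"):
            read_outline(path)

    def test_non_numeric_token_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0,0\n1,0\noops,1\n0,1\n")
        with pytest.raises(ValueError, match="bad.csv:3"):
            read_outline(path)


class TestOrientation:
    def test_clockwise_reversed(self):
        cw = SQUARE[::-1]
        std = orient_standard(cw)
        assert signed_area(std) > 0
        assert np.isclose(abs(signed_area(std)), 1.0)

    def test_idempotent(self):
        std = orient_standard(SQUARE)
        assert np.allclose(orient_standard(std), std)

    def test_centroid_at_origin_start_at_min_x(self):
        std = orient_standard(SQUARE + [5.0, -3.0])
        assert np.allclose(std.mean(axis=0), 0.0, atol=1e-12)
        assert std[0, 0] == std[:, 0].min()

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="degenerate"):
            orient_standard(line)


class TestResampling:
    def test_unit_square_p8_hits_corners_and_midpoints(self):
        std = orient_standard(SQUARE)
        res = resample_equal_arclength(std, 8)
        # spacing 0.5 along perimeter 4: corners + edge midpoints
        d = np.linalg.norm(np.diff(np.vstack([res, res[:1]]), axis=0), axis=1)
        assert np.allclose(d, 0.5)
        corners = {tuple(np.round(p, 9)) for p in std}
        hit = {tuple(np.round(p, 9)) for p in res}
        assert corners <= hit

    def test_circle_radii_preserved(self):
        th = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        circ = np.column_stack([np.cos(th), np.sin(th)])
        res = resample_equal_arclength(circ, 150)
        assert np.allclose(np.linalg.norm(res, axis=1), 1.0, atol=1e-3)

    def test_idempotent_on_equal_chord_polygon(self):
        # a regular polygon is its own equal-arc-length resampling
        th = np.linspace(0, 2 * np.pi, 150, endpoint=False)
        poly = np.column_stack([np.cos(th), np.sin(th)])
        again = resample_equal_arclength(poly, 150)
        assert np.allclose(again, poly, atol=1e-9)

    def test_contracts_toward_equal_chords_on_wings(self, wing_outline):
        # curvature makes one pass inexact but repeated passes converge
        r1 = resample_equal_arclength(wing_outline, 150)
        r2 = resample_equal_arclength(r1, 150)
        d1 = np.abs(r1 - wing_outline).max()
        d2 = np.abs(r2 - r1).max()
        assert d1 < 1e-3
        assert d2 < 0.2 * d1

    def test_small_p_rejected(self):
        with pytest.raises(ValueError):
            resample_equal_arclength(SQUARE, 4)


class TestMeasures:
    @pytest.mark.parametrize(
        "poly,area,span", [(SQUARE, 1.0, 1.0), (RECT41, 4.0, 4.0)]
    )
    def test_area_span(self, poly, area, span):
        assert np.isclose(polygon_area(poly), area)
        assert np.isclose(wing_span(poly), span)

    def test_centroid_size_unit_square(self):
        # each corner sqrt(2)/2 from the vertex centroid
        assert np.isclose(centroid_size(SQUARE), np.sqrt(2.0))

    def test_invariance_and_scaling(self, wing_outline):
        ang = 0.73
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = wing_outline @ R.T + [2.0, -1.0]
        assert np.isclose(polygon_area(moved), polygon_area(wing_outline))
        assert np.isclose(centroid_size(moved), centroid_size(wing_outline))
        scaled = wing_outline * 3.0
        assert np.isclose(polygon_area(scaled), 9.0 * polygon_area(wing_outline))
        assert np.isclose(centroid_size(scaled), 3.0 * centroid_size(wing_outline))


def _brute_force_intersects(v: np.ndarray) -> bool:
    """O(n^2) all-pairs proper-intersection / overlap oracle."""

    def orient(p, q, r):
        val = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        return 0 if val == 0 else (1 if val > 0 else -1)

    def on_segment(p, q, r):
        return (
            min(p[0], q[0]) <= r[0] <= max(p[0], q[0])
            and min(p[1], q[1]) <= r[1] <= max(p[1], q[1])
        )

    n = len(v)
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            adjacent = j == i + 1 or (i == 0 and j == n - 1)
            a, b = edges[i]
            c, d = edges[j]
            o1, o2 = orient(a, b, c), orient(a, b, d)
            o3, o4 = orient(c, d, a), orient(c, d, b)
            if adjacent:
                # only the shared endpoint may touch
                shared = tuple(b) if j == i + 1 else tuple(a)
                pts = [p for p in (a, b, c, d) if tuple(p) != shared]
                # collinear overlap beyond the shared endpoint
                if o1 == o2 == o3 == o4 == 0:
                    for p, (s, t) in [(pts[0], (c, d)), (pts[1], (a, b))]:
                        if on_segment(s, t, p) and tuple(p) != shared:
                            return True
                continue
            if o1 != o2 and o3 != o4:
                return True
            if o1 == 0 and on_segment(a, b, c):
                return True
            if o2 == 0 and on_segment(a, b, d):
                return True
            if o3 == 0 and on_segment(c, d, a):
                return True
            if o4 == 0 and on_segment(c, d, b):
                return True
    return False


class TestSelfIntersection:
    def test_convex_false(self):
        assert not is_self_intersecting(SQUARE)

    def test_bowtie_true(self):
        bow = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        assert is_self_intersecting(bow)

    def test_mid_edge_touch_true(self):
        # vertex (1,0) lies in the interior of edge (0,0)-(2,0)
        v = np.array([[0, 0], [2, 0], [2, 2], [1, 0], [0, 2]], dtype=float)
        assert is_self_intersecting(v)
        assert _brute_force_intersects(v)

    def test_agrees_with_brute_force_on_random_polygons(self):
        rng = np.random.default_rng(11)
        mismatches = 0
        for _ in range(500):
            n = rng.integers(4, 9)
            v = rng.uniform(-1, 1, size=(n, 2))
            if _brute_force_intersects(v) != is_self_intersecting(v):
                mismatches += 1
        assert mismatches == 0
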