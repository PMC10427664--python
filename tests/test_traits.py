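"""Trait assembly: body size, hull areas, cell occupancy, thermal range."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periltools import traits
from periltools.types import OccurrenceSet


class TestBodySize:
    @pytest.mark.parametrize(
        "length,height,expected",
        [(100, 100, 100.0), (4, 9, 6.0), (120.3, 60.1, math.sqrt(120.3 * 60.1))],
    )
    def test_geometric_mean(self, length, height, expected):
        assert traits.body_size(length, height) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            traits.body_size(0, 10)
        with pytest.raises(ValueError):
            traits.body_size(10, -1)


def brute_force_hull_area(points):
    """O(n^3) hull: keep points that are vertices of the hull (some point set
    lies strictly on one side of every hull edge), then shoelace on the
    angularly sorted vertices."""
    pts = list(dict.fromkeys(points))
    if len(pts) < 3:
        return 0.0
    # (a, b) is a hull edge iff every other point lies left of (or on) it
    edges = []
    for a in pts:
        for b in pts:
            if a == b:
                continue
            cross_signs = []
            for c in pts:
                if c in (a, b):
                    continue
                cr = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                cross_signs.append(cr)
            if all(s >= -1e-12 for s in cross_signs):
                edges.append((a, b))
    if not edges:
        return 0.0
    verts = {e[0] for e in edges} | {e[1] for e in edges}
    cx = sum(v[0] for v in verts) / len(verts)
    cy = sum(v[1] for v in verts) / len(verts)
    ordered = sorted(verts, key=lambda v: math.atan2(v[1] - cy, v[0] - cx))
    area = 0.0
    for i in range(len(ordered)):
        x1, y1 = ordered[i]
        x2, y2 = ordered[(i + 1) % len(ordered)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestConvexHull:
    def test_unit_square(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert traits.convex_hull_area(pts) == pytest.approx(1.0)

    def test_collinear_degenerate(self):
        assert traits.convex_hull_area([(0, 0), (1, 1), (2, 2)]) == 0.0
        assert traits.convex_hull_area([(3, 4)]) == 0.0

    def test_matches_brute_force_hull(self):
        rng = np.random.default_rng(11)
        pts = [tuple(p) for p in rng.uniform(0, 100, size=(25, 2))]
        assert traits.convex_hull_area(pts) == pytest.approx(
            brute_force_hull_area(pts), abs=1e-9
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            traits.convex_hull_area([(0, 0), (float("nan"), 1)])

    @given(
        st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=3,
            max_size=12,
        ),
        st.floats(0, 2 * math.pi),
        st.tuples(st.floats(-500, 500), st.floats(-500, 500)),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rigid_motion_and_order_invariance(self, pts, angle, shift):
        base = traits.convex_hull_area(pts)
        c, s = math.cos(angle), math.sin(angle)
        moved = [(c * x - s * y + shift[0], s * x + c * y + shift[1]) for x, y in pts]
        assert traits.convex_hull_area(moved) == pytest.approx(
            base, rel=1e-6, abs=1e-6
        )
        assert traits.convex_hull_area(list(reversed(pts))) == pytest.approx(base)

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=1,
            max_size=10,
        ),
        st.tuples(st.floats(0, 100), st.floats(0, 100)),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_range_area_monotone_under_added_points(self, pts, extra):
        occ1 = OccurrenceSet("a", points=pts)
        occ2 = OccurrenceSet("a", points=pts + [extra])
        assert traits.geographic_range_area(occ2) >= traits.geographic_range_area(occ1)


class TestGeographicRangeArea:
    def test_single_point_floor(self):
        occ = OccurrenceSet("a", points=[(10.0, 20.0)])
        assert traits.geographic_range_area(occ) == 100.0

    def test_above_floor_passthrough(self):
        occ = OccurrenceSet("a", points=[(0, 0), (50, 0), (50, 50), (0, 50)])
        assert traits.geographic_range_area(occ) == 2500.0

    def test_collinear_falls_to_floor(self):
        occ = OccurrenceSet("a", points=[(0, 0), (30, 30), (60, 60)])
        assert traits.geographic_range_area(occ) == 100.0

    def test_override(self):
        occ = OccurrenceSet("a", points=[(0, 0)])
        assert traits.geographic_range_area(occ, override=42.0) == 42.0
        with pytest.raises(ValueError):
            traits.geographic_range_area(occ, override=-1.0)


class TestOccupiedCells:
    def test_point_at_centroid(self, small_grid):
        occ = OccurrenceSet("a", points=[(75.0, 25.0)])
        assert traits.occupied_cells(occ, small_grid) == {"c1_0"}

    def test_hull_spanning_2x2_exactly(self, small_grid):
        eps = 1e-9
        occ = OccurrenceSet(
            "a",
            points=[(eps, eps), (100 - eps, eps), (100 - eps, 100 - eps), (eps, 100 - eps)],
        )
        assert traits.occupied_cells(occ, small_grid) == {
            "c0_0", "c1_0", "c0_1", "c1_1"
        }

    def test_direct_cells_passed_through(self, small_grid):
        occ = OccurrenceSet("a", cells={"c3_2"})
        assert traits.occupied_cells(occ, small_grid) == {"c3_2"}

    def test_matches_rasterization_oracle(self, small_grid):
        rng = np.random.default_rng(4)
        pts = [tuple(p) for p in rng.uniform(5, 195, size=(12, 2))]
        occ = OccurrenceSet("a", points=pts)
        got = traits.occupied_cells(occ, small_grid)
        # oracle: 1-km raster of the hull interior, point-in-polygon per pixel
        from shapely.geometry import MultiPoint, Point

        hull = MultiPoint(pts).convex_hull
        expected = set()
        for cid in small_grid.cell_ids:
            xmin, ymin, xmax, ymax = small_grid.bounds(cid)
            found = False
            for x in np.arange(xmin + 0.5, xmax, 1.0):
                for y in np.arange(ymin + 0.5, ymax, 1.0):
                    if hull.contains(Point(x, y)):
                        expected.add(cid)
                        found = True
                        break
                if found:
                    break
        assert got == expected

    def test_off_grid_returns_empty(self, small_grid):
        occ = OccurrenceSet("a", points=[(1e5, 1e5)])
        assert traits.occupied_cells(occ, small_grid) == set()


class TestThermalRange:
    def test_single_cell_zero(self, small_grid):
        assert traits.thermal_range({"c0_0"}, small_grid) == 0.0

    def test_max_minus_min(self, small_grid):
        # rows have SST 28, 26, 24
        assert traits.thermal_range({"c0_0", "c0_1", "c0_2"}, small_grid) == pytest.approx(4.0)

    def test_matches_linear_scan(self, small_grid):
        rng = np.random.default_rng(9)
        cells = list(rng.choice(small_grid.cell_ids, size=8, replace=False))
        ssts = [small_grid.sst(c) for c in cells]
        assert traits.thermal_range(cells, small_grid) == pytest.approx(
            max(ssts) - min(ssts)
        )

    def test_monotone_under_added_cells(self, small_grid):
        base = traits.thermal_range({"c0_0", "c1_0"}, small_grid)
        bigger = traits.thermal_range({"c0_0", "c1_0", "c0_2"}, small_grid)
        assert bigger >= base

    def test_unknown_cell_rejected(self, small_grid):
        with pytest.raises(KeyError):
            traits.thermal_range({"nope"}, small_grid)


class TestBathymetryImputation:
    @pytest.mark.parametrize(
        "descriptor,expected",
        [("subtidal", 5.0), ("sublittoral", 5.0), ("Shallow Water", 10.0)],
    )
    def test_known_descriptors(self, descriptor, expected):
        depth, imputed = traits.impute_min_bathymetry(descriptor)
        assert depth == expected and imputed

    def test_unknown_descriptor_absent(self):
        depth, imputed = traits.impute_min_bathymetry("bathyal")
        assert depth is None and not imputed
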