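"""Triangulation, Möller–Trumbore, linking parity, classification."""

import numpy as np
import pytest

from oracles import gauss_linking_number, segment_triangle_bruteforce, smooth_closed_curve
from rnatangle.topology import (
    linking_parity, segment_triangle_intersection, triangulate,
)


def circle(n=32, r=1.0, centre=(0, 0, 0), plane="xy"):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c = np.asarray(centre, float)
    if plane == "xy":
        pts = np.stack([r * np.cos(th), r * np.sin(th), 0 * th], axis=1)
    else:  # xz
        pts = np.stack([r * np.cos(th), 0 * th, r * np.sin(th)], axis=1)
    return pts + c


class TestTriangulate:
    def test_square_fan(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        tris, parents = triangulate(sq, max_edge=2.0)
        assert len(tris) == 4
        assert sorted(parents) == [0, 1, 2, 3]

    def test_subdivision_edge_bound(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        tris, _ = triangulate(sq, max_edge=0.5)
        edges = tris - np.roll(tris, 1, axis=1)
        assert np.sqrt((edges ** 2).sum(-1)).max() <= 0.5 + 1e-12

    def test_total_area_conserved_under_refinement(self):
        sq = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)

        def area(tris):
            e1 = tris[:, 1] - tris[:, 0]
            e2 = tris[:, 2] - tris[:, 0]
            return 0.5 * np.sqrt((np.cross(e1, e2) ** 2).sum(-1)).sum()

        coarse, _ = triangulate(sq, 5.0)
        fine, _ = triangulate(sq, 0.4)
        assert area(coarse) == pytest.approx(4.0)
        assert area(fine) == pytest.approx(4.0)

    def test_degenerate_collinear_chain(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        tris, _ = triangulate(line, 1.0)
        assert len(tris) == 0


class TestMollerTrumbore:
    TRI = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)

    def test_analytic_hit(self):
        hit = segment_triangle_intersection([0.2, 0.2, -1], [0.2, 0.2, 1], self.TRI)
        assert hit is not None
        point, orientation = hit
        assert np.allclose(point, [0.2, 0.2, 0.0])
        assert orientation in (-1, 1)

    def test_outside_barycentric_range(self):
        assert segment_triangle_intersection([2, 2, -1], [2, 2, 1], self.TRI) is None

    def test_opposite_directions_have_opposite_orientation(self):
        down = segment_triangle_intersection([0.2, 0.2, 1], [0.2, 0.2, -1], self.TRI)
        up = segment_triangle_intersection([0.2, 0.2, -1], [0.2, 0.2, 1], self.TRI)
        assert down[1] == -up[1]

    def test_agrees_with_rasterisation_oracle(self):
        """1000 random segment/triangle pairs against the brute-force oracle.

        Near-grazing cases below the oracle's resolution are skipped; the
        verdict must agree on every other pair.
        """
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(1000):
            tri = rng.uniform(-1, 1, (3, 3))
            p0 = rng.uniform(-1.5, 1.5, 3)
            p1 = rng.uniform(-1.5, 1.5, 3)
            ours = segment_triangle_intersection(p0, p1, tri) is not None
            # skip triangles too small for the oracle's resolution
            normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            area = 0.5 * np.linalg.norm(normal)
            if area < 0.05:
                continue
            s0 = (p0 - tri[0]) @ normal
            s1 = (p1 - tri[0]) @ normal
            nhat = normal / np.linalg.norm(normal)
            if min(abs((p0 - tri[0]) @ nhat), abs((p1 - tri[0]) @ nhat)) < 0.08:
                continue  # glancing incidence: the oracle cannot adjudicate
            if s0 * s1 > 0:
                # both endpoints on one side: a crossing is impossible, and
                # any oracle "hit" is a graze above the surface
                assert not ours
                checked += 1
                continue
            # crossing point within a thin band of the triangle's edge:
            # Euclidean and barycentric tolerances disagree there
            t_cross = s0 / (s0 - s1)
            pt = p0 + t_cross * (p1 - p0)

            def seg_dist(a, b):
                d = b - a
                tt = np.clip((pt - a) @ d / (d @ d), 0.0, 1.0)
                return np.linalg.norm(pt - (a + tt * d))

            rim = min(seg_dist(tri[0], tri[1]), seg_dist(tri[1], tri[2]),
                      seg_dist(tri[2], tri[0]))
            if rim < 0.05:
                continue  # too close to the triangle's rim to adjudicate
            oracle_loose = segment_triangle_bruteforce(p0, p1, tri, tol=0.09)
            oracle_tight = segment_triangle_bruteforce(p0, p1, tri, tol=0.015)
            if oracle_loose != oracle_tight:
                continue  # grazing: oracle resolution-limited
            assert ours == oracle_tight
            checked += 1
        assert checked > 700


class TestLinkingParity:
    def test_hopf_link(self):
        a = circle(plane="xy")
        b = circle(plane="xz", centre=(1, 0, 0))
        assert abs(linking_parity(a, b)) == 1

    def test_unlinked(self):
        a = circle(plane="xy")
        b = circle(plane="xz", centre=(3, 0, 0))
        assert linking_parity(a, b) == 0

    def test_antisymmetry_of_magnitude(self):
        a = circle(plane="xy", r=2.0)
        b = circle(plane="xz", centre=(2, 0, 0), r=2.0)
        assert abs(linking_parity(a, b)) == abs(linking_parity(b, a))

    def test_matches_gauss_integral_on_random_loops(self):
        """200+ random smooth loop pairs against the Gauss-integral oracle."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(260):
            a = smooth_closed_curve(rng)
            b = smooth_closed_curve(rng) + rng.normal(0, 3, 3)
            value, dmin = gauss_linking_number(a, b)
            if abs(value - round(value)) > 0.2 or dmin < 0.5:
                continue  # ambiguous at polygon resolution
            assert abs(linking_parity(a, b)) == abs(round(value))
            checked += 1
        assert checked >= 100

    def test_rigid_motion_invariance(self):
        from rnatangle.geometry import rotation_about_axis

        a = circle(plane="xy")
        b = circle(plane="xz", centre=(1, 0, 0))
        R = rotation_about_axis([1, 1, 0], 0.8)
        t = np.array([3.0, -2.0, 5.0])
        assert abs(linking_parity(a @ R.T + t, b @ R.T + t)) == \
            abs(linking_parity(a, b))
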