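"""Exact disc/annulus clipping and minimum enclosing circles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatcorr import (
    Domain,
    annulus_area_in_domain,
    disc_area_in_domain,
    min_enclosing_circle,
)
from spatcorr.geometry import disc_areas, mec_radius_pairs, mec_radius_triplets


def pixel_count_area(center, radius, domain, h=0.1):
    """Independent numeric oracle: count pixel centers inside disc and domain."""
    x = np.arange(domain.x_min + h / 2, domain.x_max, h)
    y = np.arange(domain.y_min + h / 2, domain.y_max, h)
    xx, yy = np.meshgrid(x, y)
    inside = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    return inside.sum() * h * h


def brute_force_mec(points):
    """Exhaustive oracle: try all 2-point diameters and 3-point circumcircles."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = None

    def contains_all(cx, cy, r):
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        return np.all(d <= r * (1 + 1e-9) + 1e-12)

    if n == 1:
        return (pts[0, 0], pts[0, 1], 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            cx, cy = (pts[i] + pts[j]) / 2
            r = np.hypot(*(pts[i] - pts[j])) / 2
            if contains_all(cx, cy, r) and (best is None or r < best[2]):
                best = (cx, cy, r)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx_, cy_ = pts[k]
                d = 2 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
                if abs(d) < 1e-12:
                    continue
                a2, b2, c2 = ax**2 + ay**2, bx**2 + by**2, cx_**2 + cy_**2
                ux = (a2 * (by - cy_) + b2 * (cy_ - ay) + c2 * (ay - by)) / d
                uy = (a2 * (cx_ - bx) + b2 * (ax - cx_) + c2 * (bx - ax)) / d
                r = np.hypot(ax - ux, ay - uy)
                if contains_all(ux, uy, r) and (best is None or r < best[2]):
                    best = (ux, uy, r)
    return best


class TestDiscArea:
    @pytest.mark.parametrize(
        "center,radius,expected",
        [
            ((500, 500), 10, 100 * math.pi),  # wholly interior
            ((0, 500), 10, 50 * math.pi),  # half-disc on an edge
            ((0, 0), 10, 25 * math.pi),  # quarter-disc at a corner
            ((1000, 1000), 10, 25 * math.pi),  # opposite corner by symmetry
            ((500, 0), 10, 50 * math.pi),
            ((500, 500), 0, 0.0),
        ],
    )
    def test_closed_form_cases(self, center, radius, expected, unit_km_domain):
        area = disc_area_in_domain(center, radius, unit_km_domain)
        assert area == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_center_outside_domain_rejected(self, unit_km_domain):
        with pytest.raises(ValueError, match="outside"):
            disc_area_in_domain((-1, 500), 10, unit_km_domain)

    def test_negative_radius_rejected(self, unit_km_domain):
        with pytest.raises(ValueError, match="radius"):
            disc_area_in_domain((500, 500), -1, unit_km_domain)

    def test_agrees_with_pixel_counting_oracle(self, rng):
        """100 random (center, radius) cases vs fine-grid pixel counting."""
        domain = Domain(0, 60, 0, 60)
        for _ in range(100):
            center = rng.uniform(0, 60, 2)
            radius = rng.uniform(5, 30)
            exact = disc_area_in_domain(center, radius, domain)
            approx = pixel_count_area(center, radius, domain)
            assert abs(exact - approx) / exact < 1e-3

    def test_monotone_and_continuous_in_radius(self, rng, unit_km_domain):
        center = np.array([[3.0, 997.0]])
        radii = np.linspace(0, 50, 400)
        areas = disc_areas(center, radii, unit_km_domain)[0]
        assert np.all(np.diff(areas) >= 0)
        assert np.max(np.abs(np.diff(areas))) < 2 * math.pi * 50 * (radii[1] - radii[0]) * 1.01

    def test_disc_spanning_whole_domain(self, small_domain):
        # radius larger than the diagonal: intersection is the full rectangle
        area = disc_area_in_domain((50, 50), 1000, small_domain)
        assert area == pytest.approx(small_domain.area(), rel=1e-12)


class TestAnnulusArea:
    def test_interior_annulus(self, unit_km_domain):
        a = annulus_area_in_domain((500, 500), 20, 10, unit_km_domain)
        assert a == pytest.approx(500 * math.pi, rel=1e-12)

    def test_corner_annulus_is_quarter(self, unit_km_domain):
        a = annulus_area_in_domain((0, 0), 20, 10, unit_km_domain)
        assert a == pytest.approx(125 * math.pi, rel=1e-12)

    def test_inner_zero_equals_disc(self, rng, unit_km_domain):
        for _ in range(10):
            c = rng.uniform(0, 1000, 2)
            r = rng.uniform(1, 80)
            assert annulus_area_in_domain(c, 0, r, unit_km_domain) == pytest.approx(
                disc_area_in_domain(c, r, unit_km_domain), rel=1e-10
            )

    def test_nonpositive_width_rejected(self, unit_km_domain):
        with pytest.raises(ValueError, match="width"):
            annulus_area_in_domain((500, 500), 20, 0, unit_km_domain)


class TestMinEnclosingCircle:
    def test_two_point_diameter(self):
        c = min_enclosing_circle([(0, 0), (2, 0)])
        assert c.center == pytest.approx((1, 0))
        assert c.radius == pytest.approx(1.0)

    def test_equilateral_triangle_circumradius(self):
        pts = [(0, 0), (1, 0), (0.5, math.sqrt(3) / 2)]
        assert min_enclosing_circle(pts).radius == pytest.approx(1 / math.sqrt(3))

    def test_interior_point_ignored(self):
        c = min_enclosing_circle([(0, 0), (4, 0), (1, 1)])
        assert c.center == pytest.approx((2, 0))
        assert c.radius == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one point"):
            min_enclosing_circle(np.empty((0, 2)))

    def test_matches_brute_force_on_random_small_sets(self, rng):
        for n in range(1, 9):
            for _ in range(25):
                pts = rng.uniform(0, 10, (n, 2))
                got = min_enclosing_circle(pts)
                want = brute_force_mec(pts)
                assert got.radius == pytest.approx(want[2], rel=1e-9, abs=1e-9)
                d = np.hypot(pts[:, 0] - got.center[0], pts[:, 1] - got.center[1])
                assert np.all(d <= got.radius * (1 + 1e-9) + 1e-12)

    def test_radius_bounds_for_triples(self, rng):
        for _ in range(50):
            pts = rng.uniform(0, 10, (3, 2))
            dmax = max(
                np.hypot(*(pts[i] - pts[j])) for i in range(3) for j in range(i + 1, 3)
            )
            r = min_enclosing_circle(pts).radius
            assert dmax / 2 - 1e-9 <= r <= dmax / math.sqrt(3) + 1e-9

    def test_radius_shrinks_when_point_removed(self, rng):
        pts = rng.uniform(0, 10, (8, 2))
        full = min_enclosing_circle(pts).radius
        for i in range(8):
            sub = np.delete(pts, i, axis=0)
            assert min_enclosing_circle(sub).radius <= full + 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_containment_property(self, points):
        pts = np.asarray(points)
        c = min_enclosing_circle(pts)
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        assert np.all(d <= c.radius * (1 + 1e-9) + 1e-9)
        want = brute_force_mec(pts)
        assert c.radius == pytest.approx(want[2], rel=1e-8, abs=1e-8)


class TestVectorizedMEC:
    def test_pairs_are_half_distances(self, rng):
        a = rng.uniform(0, 100, (50, 2))
        b = rng.uniform(0, 100, (50, 2))
        r = mec_radius_pairs(a, b)
        assert r == pytest.approx(np.hypot(*(a - b).T) / 2)

    def test_triplets_match_welzl(self, rng):
        a = rng.uniform(0, 100, (200, 2))
        b = rng.uniform(0, 100, (200, 2))
        c = rng.uniform(0, 100, (200, 2))
        r = mec_radius_triplets(a, b, c)
        for i in range(200):
            assert r[i] == pytest.approx(
                min_enclosing_circle(np.stack([a[i], b[i], c[i]])).radius, rel=1e-9
            )

    def test_collinear_triplets(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[5.0, 0.0]])
        c = np.array([[10.0, 0.0]])
        assert mec_radius_triplets(a, b, c)[0] == pytest.approx(5.0)

    def test_degenerate_identical_points(self):
        p = np.array([[3.0, 4.0]])
        assert mec_radius_triplets(p, p, p)[0] == pytest.approx(0.0, abs=1e-12)
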