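"""Exact planar geometry shared by all statistics.

Two primitives underpin every correlation function in this package:

* the area of a disc (or annulus) clipped to the rectangular study
  domain — the edge-correction term ``A_r(x_i)`` that removes boundary
  bias from PCF-type ratios; and
* the minimum enclosing circle (MEC) of a point set — the
  "neighbourhood size" of a k-tuple in the NCF.

Disc–rectangle intersection is computed in closed form by integrating
the disc's chord length over the rectangle (an inclusion–exclusion of
quadrant integrals), so every downstream statistic is deterministic and
exact to floating-point rounding. MECs use Welzl's randomized
incremental algorithm for general point sets, with direct vectorized
formulas for the pair/triplet streams the NCF generates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pattern import Domain

__all__ = [
    "Circle",
    "disc_area_in_domain",
    "disc_areas",
    "annulus_area_in_domain",
    "annulus_areas",
    "min_enclosing_circle",
    "mec_radius_pairs",
    "mec_radius_triplets",
]

#: relative containment tolerance for floating-point boundary points
MEC_TOL = 1e-9


@dataclass(frozen=True)
class Circle:
    """A circle given by center (μm) and radius (μm, >= 0)."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be non-negative, got {self.radius}")

    def contains(self, point, tol: float = MEC_TOL) -> bool:
        """Closed-disc membership with relative tolerance ``tol``."""
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        slack = tol * max(self.radius, 1.0)
        return dx * dx + dy * dy <= (self.radius + slack) ** 2


# ---------------------------------------------------------------------------
# disc / annulus areas clipped to the domain
# ---------------------------------------------------------------------------


def _antideriv(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Antiderivative of the half-chord sqrt(r^2 - x^2), valid for |x| <= r."""
    g = np.sqrt(np.maximum(r * r - x * x, 0.0))
    # clip the asin argument against rounding at |x| = r
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(r > 0, np.clip(x / np.where(r > 0, r, 1.0), -1.0, 1.0), 0.0)
    return 0.5 * (x * g + r * r * np.arcsin(s))


def _quadrant_area(x: np.ndarray, y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Area of {X <= x, Y <= y} intersected with the disc of radius r at 0.

    Fully elementwise; broadcasts x, y and r together.
    """
    x, y, r = np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(y, dtype=float), np.asarray(r, dtype=float)
    )
    xc = np.clip(x, -r, r)
    G = lambda t: _antideriv(t, r)  # noqa: E731

    out = np.zeros(x.shape, dtype=float)

    # y >= r: full vertical extent, F = integral of the full chord up to xc
    m = (y >= r) & (r > 0)
    if m.any():
        out[m] = 2.0 * (G(xc)[m] - G(-r)[m])

    # 0 <= y < r: chord truncated above by y for |X| < c, full outside
    m = (y >= 0) & (y < r) & (r > 0)
    if m.any():
        c = np.sqrt(np.maximum(r * r - y * y, 0.0))
        u1 = np.clip(xc, -r, -c)
        u2 = np.clip(xc, -c, c)
        u3 = np.clip(xc, c, r)
        a1 = 2.0 * (G(u1) - G(-r))
        a2 = y * (u2 + c) + G(u2) - G(-c)
        a3 = 2.0 * (G(u3) - G(c))
        out[m] = (a1 + a2 + a3)[m]

    # -r < y < 0: only the sliver between the lower arc and Y = y survives
    m = (y > -r) & (y < 0) & (r > 0)
    if m.any():
        c = np.sqrt(np.maximum(r * r - y * y, 0.0))
        u = np.clip(xc, -c, c)
        out[m] = (y * (u + c) + G(u) - G(-c))[m]

    # y <= -r or r == 0: zero (already initialized)
    return out


def disc_areas(centers: np.ndarray, radii, domain: Domain) -> np.ndarray:
    """Areas of discs clipped to the domain rectangle, vectorized.

    Parameters
    ----------
    centers
        (N, 2) disc centers.
    radii
        Scalar or (M,) radii; broadcast against the centers.

    Returns
    -------
    (N,) array for scalar radii, else (N, M).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii_arr = np.asarray(radii, dtype=float)
    scalar_r = radii_arr.ndim == 0
    r = radii_arr.reshape(1, -1)
    cx = centers[:, :1]
    cy = centers[:, 1:2]

    x0 = domain.x_min - cx
    x1 = domain.x_max - cx
    y0 = domain.y_min - cy
    y1 = domain.y_max - cy

    area = (
        _quadrant_area(x1, y1, r)
        - _quadrant_area(x0, y1, r)
        - _quadrant_area(x1, y0, r)
        + _quadrant_area(x0, y0, r)
    )
    area = np.maximum(area, 0.0)
    return area[:, 0] if scalar_r else area


def disc_area_in_domain(center, radius: float, domain: Domain) -> float:
    """Exact area of the closed disc intersected with the domain rectangle.

    Equals ``pi * radius**2`` when the disc is wholly interior; continuous
    and non-decreasing in ``radius``. The center must lie inside the
    (closed) domain.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    center = np.asarray(center, dtype=float)
    if not domain.contains(center[None, :])[0]:
        raise ValueError(f"center {tuple(center)} lies outside the domain")
    return float(disc_areas(center[None, :], float(radius), domain)[0])


def annulus_areas(centers: np.ndarray, inner_radii, width: float, domain: Domain) -> np.ndarray:
    """Clipped annulus areas for many centers and inner radii at once."""
    if width <= 0:
        raise ValueError(f"annulus width must be positive, got {width}")
    inner = np.asarray(inner_radii, dtype=float)
    return disc_areas(centers, inner + width, domain) - disc_areas(centers, inner, domain)


def annulus_area_in_domain(center, inner_radius: float, width: float, domain: Domain) -> float:
    """Area of the annulus [inner, inner+width) clipped to the domain."""
    if width <= 0:
        raise ValueError(f"annulus width must be positive, got {width}")
    if inner_radius < 0:
        raise ValueError(f"inner radius must be non-negative, got {inner_radius}")
    return disc_area_in_domain(center, inner_radius + width, domain) - disc_area_in_domain(
        center, inner_radius, domain
    )


# ---------------------------------------------------------------------------
# minimum enclosing circles
# ---------------------------------------------------------------------------


def _circle_two(p: np.ndarray, q: np.ndarray) -> Circle:
    center = 0.5 * (p + q)
    radius = 0.5 * float(np.hypot(*(p - q)))
    return Circle((float(center[0]), float(center[1])), radius)


def _circumcircle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> Circle | None:
    """Circle through three points; None when they are (nearly) collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(ax - cx), abs(ay - cy), abs(bx - cx), abs(by - cy), 1.0)
    if abs(d) <= 1e-14 * scale * scale:
        return None
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    r = float(np.hypot(ax - ux, ay - uy))
    return Circle((float(ux), float(uy)), r)


def _mec_two_fixed(pts: np.ndarray, p: np.ndarray, q: np.ndarray) -> Circle:
    """Smallest circle through p and q enclosing pts (Welzl base case)."""
    circ = _circle_two(p, q)
    left: Circle | None = None
    right: Circle | None = None
    pq = q - p
    for s in pts:
        if circ.contains(s):
            continue
        cross = pq[0] * (s[1] - p[1]) - pq[1] * (s[0] - p[0])
        c = _circumcircle(p, q, s)
        if c is None:
            continue
        cc = np.asarray(c.center)
        cross_c = pq[0] * (cc[1] - p[1]) - pq[1] * (cc[0] - p[0])
        if cross > 0:
            if left is None or cross_c > (
                pq[0] * (left.center[1] - p[1]) - pq[1] * (left.center[0] - p[0])
            ):
                left = c
        elif cross < 0:
            if right is None or cross_c < (
                pq[0] * (right.center[1] - p[1]) - pq[1] * (right.center[0] - p[0])
            ):
                right = c
    if left is None and right is None:
        return circ
    if left is None:
        return right  # type: ignore[return-value]
    if right is None:
        return left
    return left if left.radius <= right.radius else right


def _mec_one_fixed(pts: np.ndarray, p: np.ndarray) -> Circle:
    """Smallest circle through p enclosing pts[:i], incrementally."""
    circ = Circle((float(p[0]), float(p[1])), 0.0)
    for i, q in enumerate(pts):
        if not circ.contains(q):
            circ = _mec_two_fixed(pts[:i], p, q)
    return circ


def min_enclosing_circle(points: Sequence | np.ndarray, seed: int = 0) -> Circle:
    """Minimum enclosing circle of a point set (Welzl, expected linear time).

    Every input point lies within the returned radius up to a relative
    tolerance of 1e-9; the circle is determined by at most 3 input points
    on its boundary. ``seed`` only fixes the internal shuffle order and
    never changes the (unique) result.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("min_enclosing_circle requires at least one point")
    if pts.shape[1] != 2:
        raise ValueError(f"points must be (N, 2), got {pts.shape}")
    if pts.shape[0] == 1:
        return Circle((float(pts[0, 0]), float(pts[0, 1])), 0.0)
    rng = np.random.default_rng(seed)
    pts = pts[rng.permutation(pts.shape[0])]
    circ = _circle_two(pts[0], pts[1])
    for i in range(2, pts.shape[0]):
        if not circ.contains(pts[i]):
            circ = _mec_one_fixed(pts[:i], pts[i])
    return circ


def mec_radius_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """MEC radii for point pairs: half the pairwise distance. Vectorized."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return 0.5 * np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])


def mec_radius_triplets(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """MEC radii for point triplets, vectorized and exact.

    For each triplet the MEC is either the diametral circle of the most
    distant pair (when it contains the third point, including all
    collinear cases) or the circumcircle of the triangle.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    pts = np.stack([a, b, c], axis=1)  # (M, 3, 2)

    d2 = np.empty((a.shape[0], 3))
    d2[:, 0] = np.sum((b - c) ** 2, axis=1)  # pair opposite a
    d2[:, 1] = np.sum((a - c) ** 2, axis=1)  # pair opposite b
    d2[:, 2] = np.sum((a - b) ** 2, axis=1)  # pair opposite c

    far = np.argmax(d2, axis=1)  # index of the point opposite the longest edge
    idx = np.arange(a.shape[0])
    p = pts[idx, (far + 1) % 3]  # endpoints of the longest edge
    q = pts[idx, (far + 2) % 3]
    s = pts[idx, far]  # remaining point
    mid = 0.5 * (p + q)
    half = 0.5 * np.sqrt(d2[idx, far])
    inside = np.sum((s - mid) ** 2, axis=1) <= (half * (1.0 + MEC_TOL)) ** 2 + MEC_TOL

    radii = half.copy()
    out = ~inside
    if out.any():
        # circumradius R = (|e1| |e2| |e3|) / (4 * triangle area)
        aa, bb, cc = a[out], b[out], c[out]
        e1 = np.sqrt(np.sum((bb - cc) ** 2, axis=1))
        e2 = np.sqrt(np.sum((aa - cc) ** 2, axis=1))
        e3 = np.sqrt(np.sum((aa - bb) ** 2, axis=1))
        area2 = np.abs(
            (bb[:, 0] - aa[:, 0]) * (cc[:, 1] - aa[:, 1])
            - (cc[:, 0] - aa[:, 0]) * (bb[:, 1] - aa[:, 1])
        )
        radii[out] = e1 * e2 * e3 / (2.0 * area2)
    return radii
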