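"""Topographical correlation maps (TCMs).

The cross-PCF summarizes correlation between two cell types with a single
curve; the TCM resolves it spatially. Each point i of type A receives a
local correlation mark

    Gamma_i = [ n_B(x_i, r) / A_r(x_i) ] / ( N_B / |D| ),

the ratio of the local density of B points within radius r of x_i
(disc-area edge-corrected) to the global B density — a local indicator
of spatial association with Gamma = 1 at the CSR level. Because Gamma is
a fold ratio (3x enrichment gives 3, 3x depletion gives 1/3), it is
linearized to Gamma' with Gamma'(1) = 0, symmetric fold changes
(3 -> +2, 1/3 -> -2) and saturation at +/-(alpha - 1). The TCM surface
is the sum of Gaussian kernels of width sigma centered at the A points,
each scaled by its Gamma':

    TCM_{AB}(x) = sum_{i in A} Gamma'_i exp(-|x - x_i|^2 / (2 sigma^2)).

Positive regions indicate locally elevated A-B association relative to
CSR, negative regions local exclusion. The map is asymmetric: kernels
are centered on A points, so TCM_{AB} != TCM_{BA} in general.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import disc_areas
from .pattern import PointPattern

__all__ = ["LocalGamma", "TCMSurface", "local_gamma", "linearize_gamma", "tcm_surface"]


@dataclass
class LocalGamma:
    """Per-point local correlation marks for one (A, B) mark pair."""

    point_indices: np.ndarray  # indices into the pattern of the A points
    gamma: np.ndarray  # >= 0
    gamma_linear: np.ndarray  # in [-(alpha-1), alpha-1]
    r_tcm: float
    alpha: float
    mark_a: object = None
    mark_b: object = None


@dataclass
class TCMSurface:
    """Raster of summed, Gamma'-scaled Gaussian kernels over the domain."""

    x: np.ndarray  # grid node x coordinates (nx,)
    y: np.ndarray  # grid node y coordinates (ny,)
    values: np.ndarray  # (ny, nx), row i at y[i]
    r_tcm: float
    sigma: float
    alpha: float
    grid_spacing: float
    mark_a: object = None
    mark_b: object = None
    meta: dict = field(default_factory=dict)

    def to_long_dataframe(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "value": self.values.ravel()}
        )

    def metadata(self) -> dict:
        return {
            "statistic": "tcm",
            "mark_a": str(self.mark_a),
            "mark_b": str(self.mark_b),
            "r_tcm": self.r_tcm,
            "sigma": self.sigma,
            "alpha": self.alpha,
            "grid_spacing": self.grid_spacing,
            **self.meta,
        }

    def save(self, raster_path, sidecar_path=None) -> None:
        """Write the raster (TIFF by extension, else text matrix) + JSON sidecar."""
        raster_path = str(raster_path)
        if raster_path.lower().endswith((".tif", ".tiff")):
            import tifffile

            tifffile.imwrite(raster_path, self.values.astype(np.float32))
        else:
            np.savetxt(raster_path, self.values)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


def local_gamma(
    pattern: PointPattern, mark_a, mark_b, r_tcm: float = 50.0
) -> LocalGamma:
    """Local A-to-B correlation Gamma for every point with mark A.

    ``Gamma_i`` compares the density of B points within ``r_tcm`` of the
    A point (edge-corrected by the disc area inside the domain) to the
    global B density N_B / |D|; 1 is the CSR level. A point carrying both
    marks never counts itself.
    """
    if r_tcm <= 0:
        raise ValueError(f"r_tcm must be positive, got {r_tcm}")
    mask_a = pattern.mask(mark_a)
    mask_b = pattern.mask(mark_b)
    n_b = int(mask_b.sum())
    if n_b == 0:
        raise ValueError(f"no points with mark {mark_b!r}")

    idx_a = np.nonzero(mask_a)[0]
    pts_a = pattern.coords[idx_a]
    idx_b = np.nonzero(mask_b)[0]
    pts_b = pattern.coords[idx_b]

    tree_b = cKDTree(pts_b)
    counts = np.asarray(tree_b.query_ball_point(pts_a, r_tcm, return_length=True), dtype=float)
    # self-exclusion for points carrying both marks: the query counted them
    both = np.isin(idx_a, idx_b)
    counts[both] -= 1.0

    areas = disc_areas(pts_a, float(r_tcm), pattern.domain)
    gamma = (counts / areas) / (n_b / pattern.domain.area())
    return LocalGamma(
        point_indices=idx_a,
        gamma=gamma,
        gamma_linear=linearize_gamma(gamma, alpha=5.0),
        r_tcm=float(r_tcm),
        alpha=5.0,
        mark_a=mark_a,
        mark_b=mark_b,
    )


def linearize_gamma(gamma, alpha: float = 5.0):
    """Fold-change-symmetric linearization Gamma' of the local ratio Gamma.

    Gamma' = min(Gamma, alpha) - 1            for Gamma >= 1
    Gamma' = 1 - min(1 / Gamma, alpha)        for 0 < Gamma < 1
    Gamma' = -(alpha - 1)                     for Gamma = 0

    so Gamma = 1 maps to 0, k-fold enrichment and k-fold depletion map to
    +/-(k - 1), and the map saturates at +/-(alpha - 1) — alpha is the
    maximal fold change the transform resolves. Accepts scalars or arrays.
    """
    if alpha <= 1:
        raise ValueError(f"alpha must exceed 1, got {alpha}")
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(g > 0, 1.0 / np.where(g > 0, g, 1.0), np.inf)
    out = np.where(g >= 1.0, np.minimum(g, alpha) - 1.0, 1.0 - np.minimum(inv, alpha))
    if np.isscalar(gamma) or np.ndim(gamma) == 0:
        return float(out)
    return out


def tcm_surface(
    pattern: PointPattern,
    mark_a,
    mark_b,
    r_tcm: float = 50.0,
    sigma: float | None = None,
    grid_spacing: float = 10.0,
    alpha: float = 5.0,
) -> TCMSurface:
    """Topographical correlation map TCM_{AB} on a regular raster.

    Kernels are unnormalized Gaussians (peak amplitude Gamma'_i) of
    standard deviation ``sigma`` (default r_tcm / 2, so the ~2 sigma
    kernel support matches the correlation radius). Raster nodes lie on a
    regular grid anchored at the domain's lower-left corner, boundaries
    inclusive.
    """
    if grid_spacing <= 0:
        raise ValueError(f"grid_spacing must be positive, got {grid_spacing}")
    if sigma is None:
        sigma = r_tcm / 2.0
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")

    dom = pattern.domain
    x = np.arange(dom.x_min, dom.x_max + grid_spacing * 1e-9, grid_spacing)
    y = np.arange(dom.y_min, dom.y_max + grid_spacing * 1e-9, grid_spacing)

    pattern.mask(mark_b)  # validate the counted mark before any fallback
    try:
        lg = local_gamma(pattern, mark_a, mark_b, r_tcm)
        pts_a = pattern.coords[lg.point_indices]
        gl = linearize_gamma(lg.gamma, alpha)
    except KeyError:
        # no points with mark_a: the surface is identically zero
        pts_a = np.empty((0, 2))
        gl = np.empty(0)

    values = np.zeros((y.size, x.size))
    if pts_a.shape[0]:
        inv2s2 = 1.0 / (2.0 * sigma * sigma)
        # accumulate kernels in chunks of points to bound memory
        chunk = max(1, int(2_000_000 / (x.size * y.size)) or 1)
        xx = x[None, None, :]
        yy = y[None, :, None]
        for s in range(0, pts_a.shape[0], chunk):
            px = pts_a[s : s + chunk, 0][:, None, None]
            py = pts_a[s : s + chunk, 1][:, None, None]
            w = gl[s : s + chunk][:, None, None]
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            values += np.sum(w * np.exp(-d2 * inv2s2), axis=0)

    return TCMSurface(
        x=x,
        y=y,
        values=values,
        r_tcm=float(r_tcm),
        sigma=float(sigma),
        alpha=float(alpha),
        grid_spacing=float(grid_spacing),
        mark_a=mark_a,
        mark_b=mark_b,
    )
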