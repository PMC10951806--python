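"""Weighted pair correlation functions (wPCF) for continuous marks.

The cross-PCF needs categorical marks: for a continuous mark (e.g. mean
stain intensity) an exact-match indicator is zero almost everywhere.
The wPCF replaces the indicator with a weighting kernel

    w(m, M) = max(0, 1 - |m - M| / delta)      (triangular, default)

measuring how closely a point's mark m matches a target value M;
``delta`` sets the kernel's support in mark units. For a categorical
anchor type C and a continuous mark column m,

    wPCF(M, r) = |D| / (N_C W_M) * sum_{i in C} sum_{j != i}
                 w(m_j, M) 1[d_ij in bin] / A_eps(x_i, r),

with W_M = sum_j w(m_j, M) the total weight at target M. Each row (fixed
M) reads like a cross-PCF between C and "points with mark close to M".
A two-continuous-marks variant weights both ends of each pair:

    wPCF(M1, M2, r) = |D| / (W_M1 W_M2) * sum_i sum_{j != i}
                      w1(m_i, M1) w2(m_j, M2) 1[d_ij in bin] / A_eps(x_i, r).

Points whose continuous mark is NaN carry no weight and are excluded
from the j-sums and from W_M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import annulus_areas
from .pattern import PointPattern, RadialGrid

__all__ = ["WeightingParams", "WPCFSurface", "weight", "wpcf", "wpcf_continuous"]

_PAIR_CHUNK = 50_000


@dataclass(frozen=True)
class WeightingParams:
    """Mark-space weighting kernel: half-width ``delta`` and shape."""

    delta: float
    kernel: str = "triangular"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.kernel not in ("triangular", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @staticmethod
    def from_marks(marks: np.ndarray, fraction: float = 0.1) -> "WeightingParams":
        """Default delta: a fraction (1/10) of the observed mark range."""
        finite = np.asarray(marks, dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size == 0:
            raise ValueError("no finite mark values to infer delta from")
        rng = float(finite.max() - finite.min())
        if rng == 0:
            rng = max(abs(float(finite[0])), 1.0)
        return WeightingParams(delta=fraction * rng)


def weight(m, target, params: WeightingParams):
    """Kernel weight of mark value(s) ``m`` against a target mark.

    Triangular (default): w = max(0, 1 - |m - M| / delta), so w(M, M) = 1
    and w = 0 exactly when |m - M| >= delta. The Gaussian option uses
    exp(-(m - M)^2 / (2 delta^2)) (no compact support).
    """
    m_arr = np.asarray(m, dtype=float)
    t_arr = np.asarray(target, dtype=float)
    diff = np.abs(m_arr - t_arr)
    if params.kernel == "triangular":
        out = np.maximum(0.0, 1.0 - diff / params.delta)
    else:
        out = np.exp(-(diff**2) / (2.0 * params.delta**2))
    out = np.where(np.isfinite(m_arr), out, 0.0)
    if np.ndim(m) == 0 and np.ndim(target) == 0:
        return float(out)
    return out


@dataclass
class WPCFSurface:
    """wPCF values on a (target mark, radius) grid.

    ``values[t, k]`` is the wPCF at target ``target_marks[t]`` and annulus
    ``r[k]``. Rows whose total weight W_M is zero are NaN (missing, never
    zero). For the two-continuous-marks variant ``values`` has shape
    (len(targets_1), len(targets_2), len(r)) and ``target_marks_2`` is set.
    """

    target_marks: np.ndarray
    r: np.ndarray
    values: np.ndarray
    weights_total: np.ndarray
    target_marks_2: np.ndarray | None = None
    weights_total_2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def row(self, target: float) -> np.ndarray:
        """Values at the target-grid entry nearest ``target``."""
        t = int(np.argmin(np.abs(self.target_marks - target)))
        return self.values[t]

    def to_long_dataframe(self) -> pd.DataFrame:
        if self.values.ndim == 2:
            tt, rr = np.meshgrid(self.target_marks, self.r, indexing="ij")
            ww = np.repeat(self.weights_total[:, None], self.r.size, axis=1)
            return pd.DataFrame(
                {
                    "target_mark": tt.ravel(),
                    "r": rr.ravel(),
                    "value": self.values.ravel(),
                    "W_M": ww.ravel(),
                }
            )
        t1, t2, rr = np.meshgrid(
            self.target_marks, self.target_marks_2, self.r, indexing="ij"
        )
        return pd.DataFrame(
            {
                "target_1": t1.ravel(),
                "target_2": t2.ravel(),
                "r": rr.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)

    def plot(self, path=None, ax=None):
        """Heatmap of the (target, radius) surface (2-D variant only)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.values.ndim != 2:
            raise ValueError("heatmap plotting supports the 2-D surface only")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        extent = [
            self.r[0],
            self.r[-1],
            self.target_marks[0],
            self.target_marks[-1],
        ]
        im = ax.imshow(
            self.values,
            origin="lower",
            aspect="auto",
            extent=extent,
            cmap="RdBu_r",
            vmin=0,
            vmax=max(2.0, np.nanmax(self.values)) if np.isfinite(self.values).any() else 2.0,
        )
        ax.set_xlabel("r (μm)")
        ax.set_ylabel("target mark M")
        plt.colorbar(im, ax=ax, label="wPCF(M, r)")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def _default_targets(marks: np.ndarray, n: int = 101) -> np.ndarray:
    finite = marks[np.isfinite(marks)]
    if finite.size == 0:
        raise ValueError("continuous mark column holds no finite values")
    lo, hi = float(finite.min()), float(finite.max())
    if lo == hi:
        return np.array([lo])
    return np.linspace(lo, hi, n)


def _weighted_pair_sums(
    centers: np.ndarray,
    center_weights: np.ndarray | None,
    others: np.ndarray,
    other_marks: np.ndarray,
    targets: np.ndarray,
    params: WeightingParams,
    grid: RadialGrid,
    domain,
    self_pairs: np.ndarray | None,
) -> np.ndarray:
    """Accumulate sum_pairs cw_i * w(m_j, M) / A_i per (target, bin).

    ``self_pairs`` maps center index -> index in ``others`` of the same
    physical point (or -1), used to exclude i == j pairs.
    ``center_weights`` is a (n_centers, n_targets_1) matrix for the
    two-continuous variant, or None for unit center weights.
    """
    n_t = targets.size
    nb = grid.n_bins
    first_dim = 1 if center_weights is None else center_weights.shape[1]
    acc = np.zeros((first_dim, n_t, nb))
    if centers.shape[0] == 0 or others.shape[0] == 0:
        return acc

    r_cut = float(grid.r_values[-1] + grid.width)
    pairs = cKDTree(centers).query_ball_tree(cKDTree(others), r_cut)
    i_idx = np.fromiter(
        (i for i, js in enumerate(pairs) for _ in js), dtype=int, count=sum(map(len, pairs))
    )
    j_idx = np.fromiter((j for js in pairs for j in js), dtype=int, count=i_idx.size)
    if self_pairs is not None:
        keep = self_pairs[i_idx] != j_idx
        i_idx, j_idx = i_idx[keep], j_idx[keep]
    # pairs whose j-mark is NaN carry zero weight
    keep = np.isfinite(other_marks[j_idx])
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    if i_idx.size == 0:
        return acc

    d = np.hypot(centers[i_idx, 0] - others[j_idx, 0], centers[i_idx, 1] - others[j_idx, 1])
    pair_sel, bin_idx = grid.bins_of_distances(d)
    if pair_sel.size == 0:
        return acc
    i_sel = i_idx[pair_sel]
    j_sel = j_idx[pair_sel]

    areas = annulus_areas(centers, grid.r_values, grid.width, domain)
    inv_a = 1.0 / areas[i_sel, bin_idx]

    for s in range(0, i_sel.size, _PAIR_CHUNK):
        e = min(s + _PAIR_CHUNK, i_sel.size)
        wj = weight(other_marks[j_sel[s:e], None], targets[None, :], params)  # (chunk, n_t)
        contrib = wj * inv_a[s:e, None]
        if center_weights is None:
            np.add.at(acc[0].T, bin_idx[s:e], contrib)
        else:
            cw = center_weights[i_sel[s:e]]  # (chunk, n_t1)
            block = cw[:, :, None] * contrib[:, None, :]  # (chunk, n_t1, n_t)
            np.add.at(np.moveaxis(acc, 2, 0), bin_idx[s:e], block)
    return acc


def wpcf(
    pattern: PointPattern,
    categorical_mark,
    continuous_column: str,
    target_grid: np.ndarray | None = None,
    radial_grid: RadialGrid | None = None,
    params: WeightingParams | None = None,
) -> WPCFSurface:
    """wPCF between a categorical anchor type and a continuous mark.

    Defaults: 101 evenly spaced targets spanning the observed mark range
    and ``delta`` equal to one tenth of that range. Rows with zero total
    weight are NaN. Self-pairs (the anchor point paired with itself) are
    excluded.
    """
    if radial_grid is None:
        radial_grid = RadialGrid()
    marks = pattern.continuous(continuous_column)
    if params is None:
        params = WeightingParams.from_marks(marks)
    if target_grid is None:
        target_grid = _default_targets(marks)
    targets = np.asarray(target_grid, dtype=float)

    centers = pattern.points_of(categorical_mark)
    n_c = centers.shape[0]
    idx_c = np.nonzero(pattern.mask(categorical_mark))[0]

    w_total = weight(marks[:, None], targets[None, :], params).sum(axis=0)  # (n_t,)
    if not np.any(w_total > 0):
        raise ValueError("every target has zero total weight W_M")

    sums = _weighted_pair_sums(
        centers,
        None,
        pattern.coords,
        marks,
        targets,
        params,
        radial_grid,
        pattern.domain,
        self_pairs=idx_c,
    )[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(
            w_total[:, None] > 0,
            pattern.domain.area() / (n_c * w_total[:, None]) * sums,
            np.nan,
        )
    return WPCFSurface(
        target_marks=targets,
        r=radial_grid.r_values,
        values=values,
        weights_total=w_total,
        meta={
            "statistic": "wpcf",
            "categorical_mark": str(categorical_mark),
            "continuous_column": continuous_column,
            "delta": params.delta,
            "kernel": params.kernel,
            "dr": radial_grid.dr,
            "annulus_width": radial_grid.width,
        },
    )


def wpcf_continuous(
    pattern: PointPattern,
    column_1: str,
    column_2: str,
    targets_1: np.ndarray | None = None,
    targets_2: np.ndarray | None = None,
    radial_grid: RadialGrid | None = None,
    params_1: WeightingParams | None = None,
    params_2: WeightingParams | None = None,
    n_targets: int = 26,
) -> WPCFSurface:
    """wPCF between two continuous mark columns.

    Both pair ends are kernel-weighted; the two columns may use different
    ``delta`` values since their ranges can differ. Default target grids
    use ``n_targets`` points per axis (coarser than the 2-D variant: the
    output is a 3-D block).
    """
    if radial_grid is None:
        radial_grid = RadialGrid()
    m1 = pattern.continuous(column_1)
    m2 = pattern.continuous(column_2)
    if params_1 is None:
        params_1 = WeightingParams.from_marks(m1)
    if params_2 is None:
        params_2 = WeightingParams.from_marks(m2)
    t1 = np.asarray(
        _default_targets(m1, n_targets) if targets_1 is None else targets_1, dtype=float
    )
    t2 = np.asarray(
        _default_targets(m2, n_targets) if targets_2 is None else targets_2, dtype=float
    )

    w1_total = weight(m1[:, None], t1[None, :], params_1).sum(axis=0)
    w2_total = weight(m2[:, None], t2[None, :], params_2).sum(axis=0)

    center_w = weight(m1[:, None], t1[None, :], params_1)  # (N, n_t1)
    sums = _weighted_pair_sums(
        pattern.coords,
        center_w,
        pattern.coords,
        m2,
        t2,
        params_2,
        radial_grid,
        pattern.domain,
        self_pairs=np.arange(pattern.n_points),
    )  # (n_t1, n_t2, nb)

    denom = w1_total[:, None, None] * w2_total[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, pattern.domain.area() / denom * sums, np.nan)
    if pattern.n_points < 2:
        values[:] = np.nan  # a single point carries no pair information
    return WPCFSurface(
        target_marks=t1,
        r=radial_grid.r_values,
        values=values,
        weights_total=w1_total,
        target_marks_2=t2,
        weights_total_2=w2_total,
        meta={
            "statistic": "wpcf_continuous",
            "column_1": column_1,
            "column_2": column_2,
            "delta_1": params_1.delta,
            "delta_2": params_2.delta,
            "kernel": params_1.kernel,
            "dr": radial_grid.dr,
            "annulus_width": radial_grid.width,
        },
    )
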