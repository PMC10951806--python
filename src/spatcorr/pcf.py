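"""Pair correlation function and cross-PCF with annulus edge correction.

The empirical PCF g(r) compares the observed number of point pairs at
separation ~r against the expectation under complete spatial randomness
(CSR). For a categorical mark C with N_C points in a domain of area |D|,
each ordered pair (i, j) of C-points with distance d_ij in the annulus
[r, r + eps) contributes 1 / A_eps(x_i, r), where A_eps is the annulus
area clipped to the domain (edge correction), and

    g_C(r) = |D| / (N_C (N_C - 1)) * sum_{i != j} 1[d_ij in bin] / A_eps(x_i, r)

so that CSR gives g = 1, clustering g > 1 and exclusion g < 1. The
cross-PCF g_{AB}(r) is the same sum over ordered pairs with i marked A
and j marked B, normalized by N_A N_B; it reduces exactly to the PCF
when A = B (self-pairs excluded). Significance is assessed against
pointwise envelopes from CSR simulations with matched per-mark counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .geometry import annulus_areas
from .pattern import CorrelationCurve, Domain, PointPattern, RadialGrid

__all__ = ["pcf", "cross_pcf", "csr_envelope", "StatisticConfig", "Envelope"]


def _pair_sum(
    centers: np.ndarray,
    others: np.ndarray,
    grid: RadialGrid,
    domain: Domain,
    exclude_identical_index: bool,
    other_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Edge-corrected pair sums per annulus.

    Returns, for each annulus k, ``sum_pairs w_j / A(x_i, r_k, eps)`` over
    pairs (i in centers, j in others) whose distance falls in annulus k.
    ``exclude_identical_index`` drops pairs with identical index in both
    arrays (self-pairs when centers and others are the same array).
    """
    nb = grid.n_bins
    acc = np.zeros(nb)
    if centers.shape[0] == 0 or others.shape[0] == 0:
        return acc

    r_cut = float(grid.r_values[-1] + grid.width)
    tree_c = cKDTree(centers)
    tree_o = cKDTree(others)
    pairs = tree_c.query_ball_tree(tree_o, r_cut)

    i_idx = np.fromiter(
        (i for i, js in enumerate(pairs) for _ in js), dtype=int, count=sum(map(len, pairs))
    )
    j_idx = np.fromiter((j for js in pairs for j in js), dtype=int, count=i_idx.size)
    if exclude_identical_index:
        keep = i_idx != j_idx
        i_idx, j_idx = i_idx[keep], j_idx[keep]
    if i_idx.size == 0:
        return acc

    d = np.hypot(
        centers[i_idx, 0] - others[j_idx, 0], centers[i_idx, 1] - others[j_idx, 1]
    )
    pair_sel, bin_idx = grid.bins_of_distances(d)
    if pair_sel.size == 0:
        return acc
    i_sel = i_idx[pair_sel]
    j_sel = j_idx[pair_sel]

    # per-center, per-bin clipped annulus areas; computed once per distinct center
    areas = annulus_areas(centers, grid.r_values, grid.width, domain)  # (Nc, nb)
    contrib = 1.0 / areas[i_sel, bin_idx]
    if other_weights is not None:
        contrib = contrib * other_weights[j_sel]
    np.add.at(acc, bin_idx, contrib)
    return acc


def cross_pcf(pattern: PointPattern, mark_a, mark_b, grid: RadialGrid | None = None) -> CorrelationCurve:
    """Cross-type pair correlation function g_{AB}(r).

    Pairs take the first point from ``mark_a`` and the second from
    ``mark_b``; edge correction uses annuli centered on the A points, so
    g_{AB} and g_{BA} differ only through boundary terms. With
    ``mark_a == mark_b`` self-pairs are excluded and the normalization
    becomes N_C (N_C - 1), recovering :func:`pcf` exactly.
    """
    if grid is None:
        grid = RadialGrid()
    same = mark_a == mark_b
    pts_a = pattern.points_of(mark_a)
    pts_b = pattern.points_of(mark_b)
    n_a, n_b = pts_a.shape[0], pts_b.shape[0]
    if same:
        if n_a < 2:
            raise ValueError(
                f"pcf needs at least 2 points with mark {mark_a!r}, found {n_a}"
            )
        norm = n_a * (n_a - 1)
    else:
        if n_a < 1 or n_b < 1:
            raise ValueError(
                f"cross_pcf needs at least 1 point of each mark "
                f"({mark_a!r}: {n_a}, {mark_b!r}: {n_b})"
            )
        norm = n_a * n_b

    sums = _pair_sum(pts_a, pts_b, grid, pattern.domain, exclude_identical_index=same)
    value = pattern.domain.area() / norm * sums
    return CorrelationCurve(
        r=grid.r_values,
        value=value,
        statistic="pcf" if same else "cross_pcf",
        mark_a=mark_a,
        mark_b=mark_b,
        dr=grid.dr,
        annulus_width=grid.width,
    )


def pcf(pattern: PointPattern, mark, grid: RadialGrid | None = None) -> CorrelationCurve:
    """Pair correlation function g_C(r) for a single categorical mark."""
    return cross_pcf(pattern, mark, mark, grid)


# ---------------------------------------------------------------------------
# CSR simulation envelopes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatisticConfig:
    """Named configuration of a curve statistic for envelope simulation.

    ``name`` selects the statistic ('pcf' or 'cross_pcf'); marks refer to
    keys of the per-mark counts used to simulate CSR patterns.
    """

    name: str
    mark_a: object
    mark_b: object = None
    grid: RadialGrid = field(default_factory=RadialGrid)

    def evaluate(self, pattern: PointPattern) -> CorrelationCurve:
        if self.name == "pcf":
            return pcf(pattern, self.mark_a, self.grid)
        if self.name == "cross_pcf":
            b = self.mark_a if self.mark_b is None else self.mark_b
            return cross_pcf(pattern, self.mark_a, b, self.grid)
        raise ValueError(f"unknown statistic {self.name!r}")


@dataclass
class Envelope:
    """Pointwise CSR simulation envelope for a curve statistic."""

    r: np.ndarray
    low: np.ndarray
    high: np.ndarray
    quantiles: tuple[float, float]
    n_sims: int
    statistic: str = ""

    def coverage(self, curve: CorrelationCurve) -> float:
        """Fraction of radii at which ``curve`` falls inside the envelope."""
        if curve.r.shape != self.r.shape or not np.allclose(curve.r, self.r):
            raise ValueError("curve was evaluated on a different radial grid")
        ok = np.isfinite(curve.value) & np.isfinite(self.low) & np.isfinite(self.high)
        inside = (curve.value[ok] >= self.low[ok]) & (curve.value[ok] <= self.high[ok])
        return float(inside.mean()) if ok.any() else float("nan")


def csr_envelope(
    domain: Domain,
    counts_per_mark: Mapping,
    statistic: StatisticConfig | Callable[[PointPattern], CorrelationCurve],
    n_sims: int = 99,
    quantiles: tuple[float, float] = (0.025, 0.975),
    seed: int = 0,
) -> Envelope:
    """Pointwise quantile envelope of a statistic under CSR.

    Simulates ``n_sims`` CSR patterns (uniform points, fixed per-mark
    counts matching the observed pattern) and returns the empirical
    pointwise quantiles of the statistic across simulations.
    Deterministic given ``seed``.
    """
    from .synthetic import generate_csr  # local import to avoid a cycle

    if n_sims < 19:
        raise ValueError(f"n_sims must be at least 19, got {n_sims}")
    lo_q, hi_q = quantiles
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise ValueError(f"invalid quantile pair {quantiles}")
    for mark, cnt in counts_per_mark.items():
        if cnt <= 0:
            raise ValueError(f"count for mark {mark!r} must be positive, got {cnt}")

    evaluate = statistic.evaluate if isinstance(statistic, StatisticConfig) else statistic
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)

    values = None
    r = None
    name = statistic.name if isinstance(statistic, StatisticConfig) else getattr(
        statistic, "__name__", "statistic"
    )
    for k in range(n_sims):
        sim = generate_csr(domain, counts_per_mark, seed=int(seeds[k]))
        curve = evaluate(sim)
        if values is None:
            r = curve.r
            values = np.empty((n_sims, r.size))
        values[k] = curve.value

    low = np.nanquantile(values, lo_q, axis=0)
    high = np.nanquantile(values, hi_q, axis=0)
    return Envelope(r=r, low=low, high=high, quantiles=(lo_q, hi_q), n_sims=n_sims, statistic=name)
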