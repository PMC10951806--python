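"""Neighbourhood correlation function (NCF) for three or more cell types.

Pairwise statistics cannot distinguish a pattern in which cell types A, B
and C co-occur in the same neighbourhoods from one in which they only
meet pairwise. The NCF quantifies k-way colocalization directly: for
every k-tuple taking one point per mark, the "neighbourhood size" is the
radius of the tuple's minimum enclosing circle (MEC). The observed
number of tuples whose MEC radius falls in each radial bin is compared
with the number expected under CSR,

    NCF(r) = observed_count(r) / ( N_A N_B ... * p(r) ),

where p(r) is the probability that k independent uniform points in the
same domain have MEC radius in the bin, estimated by Monte-Carlo
sampling. Using the same domain for the null absorbs edge effects, so no
analytic edge correction is needed. NCF > 1 means the k types co-occur
in neighbourhoods of that radius more often than chance, < 1 less often.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import mec_radius_pairs, mec_radius_triplets, min_enclosing_circle
from .pattern import Domain, PointPattern, RadialGrid

__all__ = ["NCFCurve", "MECProbability", "triplet_mec_radii", "csr_mec_probability", "ncf"]

#: chunk size (rows of the first mark) for the triplet enumeration
_CHUNK_A = 64


@dataclass
class MECProbability:
    """Monte-Carlo estimate of the CSR MEC-radius distribution."""

    r: np.ndarray  # inner bin radii
    width: float
    pmf: np.ndarray  # P(radius in [r, r + width)) per bin
    cdf: np.ndarray  # P(radius < r + width) per bin (outer-edge cumulative)
    stderr: np.ndarray  # MC standard error of pmf per bin
    cdf_stderr: np.ndarray
    n_samples: int
    k: int
    sorted_radii: np.ndarray = field(repr=False, default=None)

    def cumulative_at(self, r: float) -> float:
        """Empirical P(MEC radius <= r)."""
        return float(np.searchsorted(self.sorted_radii, r, side="right") / self.n_samples)


@dataclass
class NCFCurve:
    """Observed/expected MEC-radius counts for a k-mark tuple statistic.

    ``value`` is NaN in bins whose CSR expectation is zero (undefined,
    reported as missing — never as 0).
    """

    r: np.ndarray
    value: np.ndarray
    observed_counts: np.ndarray
    expected_counts: np.ndarray
    mc_stderr: np.ndarray
    marks: tuple
    k: int
    n_csr_samples: int
    cumulative: bool
    dr: float = float("nan")
    annulus_width: float = float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r,
                "observed": self.observed_counts,
                "expected": self.expected_counts,
                "value": self.value,
                "mc_stderr": self.mc_stderr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def value_at(self, r: float) -> float:
        """Value in the (first) bin whose interval contains ``r``."""
        hit = (self.r <= r) & (r < self.r + (self.annulus_width or self.dr))
        idx = np.nonzero(hit)[0]
        if idx.size == 0:
            raise ValueError(f"r={r} falls in no bin of this curve")
        return float(self.value[idx[0]])


def _mec_radii_tuple_stream(point_sets: list[np.ndarray]) -> np.ndarray:
    """MEC radii for aligned tuples (one row per tuple in each array)."""
    k = len(point_sets)
    if k == 2:
        return mec_radius_pairs(point_sets[0], point_sets[1])
    if k == 3:
        return mec_radius_triplets(point_sets[0], point_sets[1], point_sets[2])
    m = point_sets[0].shape[0]
    out = np.empty(m)
    stacked = np.stack(point_sets, axis=1)  # (M, k, 2)
    for i in range(m):
        out[i] = min_enclosing_circle(stacked[i]).radius
    return out


def triplet_mec_radii(
    pattern: PointPattern, marks: Sequence, r_max: float = 300.0
) -> np.ndarray:
    """MEC radii of every k-tuple taking one point per mark, radii <= r_max.

    Tuples whose maximum pairwise distance exceeds ``2 * r_max`` are pruned
    without computing the circle; this is exact because the MEC radius is
    at least half the largest pairwise distance.
    """
    marks = list(marks)
    if len(marks) < 2:
        raise ValueError(f"need at least 2 marks, got {len(marks)}")
    if r_max <= 0:
        raise ValueError(f"r_max must be positive, got {r_max}")
    pts = [pattern.points_of(m) for m in marks]  # raises on missing marks
    cut = 2.0 * r_max

    if len(marks) == 2:
        a, b = pts
        pairs = cKDTree(a).query_ball_tree(cKDTree(b), cut)
        ia = np.fromiter(
            (i for i, js in enumerate(pairs) for _ in js),
            dtype=int,
            count=sum(map(len, pairs)),
        )
        ib = np.fromiter((j for js in pairs for j in js), dtype=int, count=ia.size)
        radii = mec_radius_pairs(a[ia], b[ib])
        return radii[radii <= r_max]

    if len(marks) == 3:
        a, b, c = pts
        d_ab = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2) <= cut
        d_ac = np.linalg.norm(a[:, None, :] - c[None, :, :], axis=2) <= cut
        d_bc = np.linalg.norm(b[:, None, :] - c[None, :, :], axis=2) <= cut
        chunks = []
        for s in range(0, a.shape[0], _CHUNK_A):
            e = min(s + _CHUNK_A, a.shape[0])
            cand = d_ab[s:e, :, None] & d_ac[s:e, None, :] & d_bc[None, :, :]
            idx = np.argwhere(cand)
            if idx.size == 0:
                continue
            radii = mec_radius_triplets(a[idx[:, 0] + s], b[idx[:, 1]], c[idx[:, 2]])
            chunks.append(radii[radii <= r_max])
        return np.concatenate(chunks) if chunks else np.empty(0)

    # general k > 3: grow index tuples mark by mark, pruning on pairwise distance
    tuples = np.arange(pts[0].shape[0])[:, None]
    for m in range(1, len(marks)):
        new = []
        cur = pts[m]
        for row in tuples:
            prev = np.stack([pts[j][row[j]] for j in range(m)])
            d = np.linalg.norm(cur[None, :, :] - prev[:, None, :], axis=2)
            ok = np.nonzero((d <= cut).all(axis=0))[0]
            if ok.size:
                new.append(
                    np.concatenate(
                        [np.repeat(row[None, :], ok.size, axis=0), ok[:, None]], axis=1
                    )
                )
        if not new:
            return np.empty(0)
        tuples = np.concatenate(new, axis=0)
    sets = [pts[j][tuples[:, j]] for j in range(len(marks))]
    radii = _mec_radii_tuple_stream(sets)
    return radii[radii <= r_max]


def csr_mec_probability(
    domain: Domain,
    k: int = 3,
    grid: RadialGrid | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
) -> MECProbability:
    """CSR MEC-radius distribution by Monte-Carlo sampling.

    Draws ``n_samples`` independent k-tuples of uniform points in the
    domain, computes each tuple's MEC radius and returns the empirical
    probability mass per radial bin together with the outer-edge
    cumulative distribution and per-bin Monte-Carlo standard errors.
    Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be at least 1, got {n_samples}")
    if grid is None:
        grid = RadialGrid()
    rng = np.random.default_rng(seed)
    sets = [
        np.column_stack(
            [
                rng.uniform(domain.x_min, domain.x_max, n_samples),
                rng.uniform(domain.y_min, domain.y_max, n_samples),
            ]
        )
        for _ in range(k)
    ]
    radii = np.sort(_mec_radii_tuple_stream(sets))

    r = grid.r_values
    lo = np.searchsorted(radii, r, side="left")
    hi = np.searchsorted(radii, r + grid.width, side="left")
    pmf = (hi - lo) / n_samples
    cdf = hi / n_samples
    stderr = np.sqrt(pmf * (1.0 - pmf) / n_samples)
    cdf_stderr = np.sqrt(cdf * (1.0 - cdf) / n_samples)
    return MECProbability(
        r=r,
        width=float(grid.width),
        pmf=pmf,
        cdf=cdf,
        stderr=stderr,
        cdf_stderr=cdf_stderr,
        n_samples=n_samples,
        k=k,
        sorted_radii=radii,
    )


def ncf(
    pattern: PointPattern,
    marks: Sequence,
    grid: RadialGrid | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    cumulative: bool = False,
) -> NCFCurve:
    """Neighbourhood correlation function for k categorical marks.

    ``value(bin) = observed / expected`` where the expectation is
    ``prod_i N_i`` times the Monte-Carlo CSR bin probability (or, with
    ``cumulative=True``, the probability of radius below the bin's outer
    edge). Bins with zero expectation are NaN (missing). Observed counts
    are deterministic; the expectation is deterministic given ``seed``.
    """
    marks = list(marks)
    if grid is None:
        grid = RadialGrid()
    r_max = float(grid.r_values[-1] + grid.width)
    radii = triplet_mec_radii(pattern, marks, r_max=r_max)
    radii = np.sort(radii)

    r = grid.r_values
    lo = np.searchsorted(radii, r, side="left")
    hi = np.searchsorted(radii, r + grid.width, side="left")
    prob = csr_mec_probability(pattern.domain, len(marks), grid, n_samples, seed)

    n_tuples = float(np.prod([pattern.count(m) for m in marks]))
    if cumulative:
        observed = hi.astype(float)
        p = prob.cdf
        p_se = prob.cdf_stderr
    else:
        observed = (hi - lo).astype(float)
        p = prob.pmf
        p_se = prob.stderr
    expected = n_tuples * p

    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(expected > 0, observed / expected, np.nan)
        # MC uncertainty of the null propagated to the ratio
        mc_stderr = np.where(p > 0, value * p_se / p, np.nan)

    return NCFCurve(
        r=r,
        value=value,
        observed_counts=observed,
        expected_counts=expected,
        mc_stderr=mc_stderr,
        marks=tuple(marks),
        k=len(marks),
        n_csr_samples=n_samples,
        cumulative=cumulative,
        dr=grid.dr,
        annulus_width=grid.width,
    )
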