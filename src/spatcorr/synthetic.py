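"""Synthetic marked point patterns for exercising the statistics.

Two cluster constructions (Thomas-type: Gaussian offspring around parent
centers, with fixed offspring counts) plus CSR:

* **Dataset I** — two cell types on a 1000x1000 μm domain. On the left
  half, 20 shared cluster centers each receive 10 points of type C1 and
  10 of type C2 (strong C1-C2 colocalization); on the right half each
  type gets its own 10 independent centers (segregated clusters). Every
  C2 point also carries a continuous mark m: low (uniform on [0, 0.5))
  for points with x < 500, high (uniform on [0.5, 1]) otherwise — so the
  mark separates mixed from pure clusters.
* **Dataset II** — three cell types A, B, C around three fixed cluster
  centers ~300 μm apart. The ``pairwise`` variant puts two types in each
  cluster (every pair co-occurs, all three never do; 50 points per
  type); the ``triplet`` variant puts all three types in every cluster
  (75 per type). Pairwise statistics cannot tell the variants apart; the
  NCF can.
* **CSR** — uniform points with fixed per-mark counts (a binomial
  process), the null model for every ratio statistic.

Gaussian offspring falling outside the domain are resampled (not
clipped), so per-mark counts are exact and there is no boundary pile-up.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .pattern import Domain, PointPattern

__all__ = ["generate_dataset_1", "generate_dataset_2", "generate_csr"]

_DEFAULT_DOMAIN = Domain(0.0, 1000.0, 0.0, 1000.0)

#: cluster Gaussian standard deviation (μm), both datasets
DEFAULT_CLUSTER_SD = 25.0

#: dataset II parent centers: a triangle of side ~300 μm
DATASET2_CENTERS = ((350.0, 350.0), (650.0, 350.0), (500.0, 610.0))


def _gaussian_cluster(
    rng: np.random.Generator, center, sd: float, n: int, domain: Domain
) -> np.ndarray:
    """n Gaussian offspring around center, resampling out-of-domain draws."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        draw = rng.normal(loc=center, scale=sd, size=(n - filled, 2))
        ok = domain.contains(draw)
        kept = draw[ok]
        out[filled : filled + kept.shape[0]] = kept
        filled += kept.shape[0]
    return out


def generate_csr(
    domain: Domain, counts_per_mark: Mapping, seed: int = 0
) -> PointPattern:
    """CSR pattern: per-mark i.i.d. uniform points with exact counts."""
    for mark, cnt in counts_per_mark.items():
        if cnt < 0:
            raise ValueError(f"count for mark {mark!r} must be non-negative, got {cnt}")
    rng = np.random.default_rng(seed)
    coords = []
    labels = []
    for mark, cnt in counts_per_mark.items():
        xy = np.column_stack(
            [
                rng.uniform(domain.x_min, domain.x_max, cnt),
                rng.uniform(domain.y_min, domain.y_max, cnt),
            ]
        )
        coords.append(xy)
        labels.extend([mark] * cnt)
    coords_arr = np.concatenate(coords) if coords else np.empty((0, 2))
    return PointPattern(coords_arr, domain, categorical_marks=labels)


def generate_dataset_1(
    seed: int = 0,
    n_shared_clusters: int = 20,
    n_independent_clusters: int = 10,
    points_per_cluster: int = 10,
    cluster_sd: float = DEFAULT_CLUSTER_SD,
    domain: Domain | None = None,
    mark_split: float = 0.5,
) -> PointPattern:
    """Dataset I: mixed clusters on the left, segregated on the right.

    Returns 300 points of each of the marks 'C1' and 'C2' (with the
    default cluster counts). C2 points carry the continuous column 'm',
    keyed on the point's own x coordinate: below the domain midline the
    mark is uniform on [0, 0.5), otherwise uniform on [0.5, 1].
    """
    if domain is None:
        domain = _DEFAULT_DOMAIN
    rng = np.random.default_rng(seed)
    x_mid = 0.5 * (domain.x_min + domain.x_max)
    left = Domain(domain.x_min, x_mid, domain.y_min, domain.y_max)
    right = Domain(x_mid, domain.x_max, domain.y_min, domain.y_max)

    coords: list[np.ndarray] = []
    labels: list[str] = []

    # left half: shared centers, both types in every cluster
    shared = np.column_stack(
        [
            rng.uniform(left.x_min, left.x_max, n_shared_clusters),
            rng.uniform(left.y_min, left.y_max, n_shared_clusters),
        ]
    )
    for center in shared:
        for mark in ("C1", "C2"):
            coords.append(_gaussian_cluster(rng, center, cluster_sd, points_per_cluster, domain))
            labels.extend([mark] * points_per_cluster)

    # right half: independent centers per type
    for mark in ("C1", "C2"):
        centers = np.column_stack(
            [
                rng.uniform(right.x_min, right.x_max, n_independent_clusters),
                rng.uniform(right.y_min, right.y_max, n_independent_clusters),
            ]
        )
        for center in centers:
            coords.append(_gaussian_cluster(rng, center, cluster_sd, points_per_cluster, domain))
            labels.extend([mark] * points_per_cluster)

    xy = np.concatenate(coords)
    labels_arr = np.asarray(labels, dtype=object)

    m = np.full(xy.shape[0], np.nan)
    is_c2 = labels_arr == "C2"
    low = is_c2 & (xy[:, 0] < x_mid)
    high = is_c2 & (xy[:, 0] >= x_mid)
    m[low] = rng.uniform(0.0, mark_split, int(low.sum()))
    m[high] = rng.uniform(mark_split, 1.0, int(high.sum()))

    return PointPattern(xy, domain, categorical_marks=labels_arr, continuous_marks={"m": m})


def generate_dataset_2(
    seed: int = 0,
    variant: str = "pairwise",
    points_per_type_per_cluster: int = 25,
    cluster_sd: float = DEFAULT_CLUSTER_SD,
    centers: Sequence = DATASET2_CENTERS,
    domain: Domain | None = None,
) -> PointPattern:
    """Dataset II: three types around three clusters ~300 μm apart.

    ``variant='pairwise'``: clusters hold (A,B), (B,C) and (A,C) — every
    pair co-occurs but no cluster holds all three types (50 per type).
    ``variant='triplet'``: every cluster holds all of A, B, C (75 per
    type).
    """
    if domain is None:
        domain = _DEFAULT_DOMAIN
    if variant == "pairwise":
        composition = [("A", "B"), ("B", "C"), ("A", "C")]
    elif variant == "triplet":
        composition = [("A", "B", "C")] * 3
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'pairwise' or 'triplet'")
    if len(centers) != len(composition):
        raise ValueError(f"expected {len(composition)} cluster centers, got {len(centers)}")

    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    labels: list[str] = []
    for center, types in zip(centers, composition):
        for mark in types:
            coords.append(
                _gaussian_cluster(
                    rng, np.asarray(center, dtype=float), cluster_sd,
                    points_per_type_per_cluster, domain,
                )
            )
            labels.extend([mark] * points_per_type_per_cluster)
    return PointPattern(np.concatenate(coords), domain, categorical_marks=labels)
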