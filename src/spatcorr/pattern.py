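"""Containers for marked point patterns and radial evaluation grids.

A :class:`PointPattern` holds cell-centroid coordinates (in μm) on a
rectangular :class:`Domain`, together with one optional categorical mark
per point (e.g. a cell-type label) and any number of named continuous
mark columns (e.g. mean stain intensities). All correlation statistics
in this package consume these two types plus a :class:`RadialGrid`, the
sequence of annuli on which curves are evaluated, and most return a
:class:`CorrelationCurve`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Domain", "PointPattern", "RadialGrid", "CorrelationCurve"]


@dataclass(frozen=True)
class Domain:
    """Axis-aligned rectangular study region, coordinates in μm."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate domain: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Membership in the closed rectangle; boundary points are inside."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )

    def translated(self, dx: float, dy: float) -> "Domain":
        return Domain(self.x_min + dx, self.x_max + dx, self.y_min + dy, self.y_max + dy)


class PointPattern:
    """A marked point pattern on a rectangular domain.

    Parameters
    ----------
    coords
        (N, 2) array of point coordinates in μm.
    domain
        Rectangular study region. Every point must lie inside it
        (closed rectangle: boundary points are valid).
    categorical_marks
        Optional length-N sequence of labels (one per point).
    continuous_marks
        Optional mapping of column name -> length-N float array. NaN is
        permitted and means "mark absent for this point".
    """

    def __init__(
        self,
        coords: np.ndarray,
        domain: Domain,
        categorical_marks: Sequence | None = None,
        continuous_marks: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (N, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        inside = domain.contains(coords)
        if coords.shape[0] and not inside.all():
            n_bad = int((~inside).sum())
            raise ValueError(f"{n_bad} point(s) lie outside the domain")
        self.coords = coords
        self.domain = domain

        n = coords.shape[0]
        if categorical_marks is not None:
            cm = np.asarray(categorical_marks, dtype=object)
            if cm.shape != (n,):
                raise ValueError(
                    f"categorical_marks has length {cm.shape}, expected ({n},)"
                )
            self.categorical_marks = cm
        else:
            self.categorical_marks = None

        self.continuous_marks: dict[str, np.ndarray] = {}
        if continuous_marks:
            for name, col in continuous_marks.items():
                col = np.asarray(col, dtype=float)
                if col.shape != (n,):
                    raise ValueError(
                        f"continuous mark {name!r} has shape {col.shape}, "
                        f"expected ({n},)"
                    )
                self.continuous_marks[name] = col

    # -- basic interface -------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_points

    def labels(self) -> list:
        """Distinct categorical marks, in order of first appearance."""
        if self.categorical_marks is None:
            return []
        return list(pd.unique(self.categorical_marks))

    def count(self, label) -> int:
        """Number of points carrying the categorical mark ``label``."""
        return int(self.mask(label).sum())

    def mask(self, label) -> np.ndarray:
        if self.categorical_marks is None:
            raise ValueError("pattern has no categorical marks")
        m = self.categorical_marks == label
        if not m.any():
            known = ", ".join(map(str, self.labels()))
            raise KeyError(f"unknown mark {label!r}; pattern has: {known}")
        return m

    def points_of(self, label) -> np.ndarray:
        """Coordinates of all points with the given categorical mark."""
        return self.coords[self.mask(label)]

    def continuous(self, column: str) -> np.ndarray:
        if column not in self.continuous_marks:
            known = ", ".join(self.continuous_marks) or "(none)"
            raise KeyError(f"unknown continuous mark {column!r}; pattern has: {known}")
        return self.continuous_marks[column]

    def to_dataframe(
        self,
        x_column: str = "x",
        y_column: str = "y",
        categorical_column: str = "cell_type",
    ) -> pd.DataFrame:
        data = {x_column: self.coords[:, 0], y_column: self.coords[:, 1]}
        if self.categorical_marks is not None:
            data[categorical_column] = self.categorical_marks
        for name, col in self.continuous_marks.items():
            data[name] = col
        return pd.DataFrame(data)

    def translated(self, dx: float, dy: float) -> "PointPattern":
        """Rigid translation of points together with the domain."""
        return PointPattern(
            self.coords + np.array([dx, dy]),
            self.domain.translated(dx, dy),
            self.categorical_marks,
            self.continuous_marks,
        )

    def with_domain(self, domain: Domain) -> "PointPattern":
        return PointPattern(self.coords, domain, self.categorical_marks, self.continuous_marks)

    def __repr__(self) -> str:  # pragma: no cover
        marks = ""
        if self.categorical_marks is not None:
            counts = ", ".join(f"{c}: {self.count(c)}" for c in self.labels())
            marks = f", marks {{{counts}}}"
        return f"<PointPattern of {self.n_points} points{marks}>"


@dataclass(frozen=True)
class RadialGrid:
    """Sequence of annuli on which correlation curves are evaluated.

    Annulus ``k`` covers separations ``[r_k, r_k + width)`` with inner
    radii ``r_k = r_start + k * dr``. With the default ``width == dr``
    the annuli tile the radial axis exactly (non-overlapping); callers
    may choose ``width < dr`` (gaps) or ``width > dr`` (overlap).

    All lengths in μm.
    """

    r_start: float = 0.0
    r_max: float = 300.0
    dr: float = 10.0
    width: float | None = None

    def __post_init__(self) -> None:
        if self.dr <= 0:
            raise ValueError(f"dr must be positive, got {self.dr}")
        w = self.dr if self.width is None else self.width
        if w <= 0:
            raise ValueError(f"annulus width must be positive, got {w}")
        if self.r_start < 0:
            raise ValueError(f"r_start must be non-negative, got {self.r_start}")
        if self.r_max <= self.r_start:
            raise ValueError("r_max must exceed r_start")
        object.__setattr__(self, "width", w)

    @property
    def r_values(self) -> np.ndarray:
        """Inner radii of the annuli."""
        n = int(np.floor((self.r_max - self.r_start) / self.dr + 1e-12)) + 1
        r = self.r_start + self.dr * np.arange(n)
        return r[r + self.width <= self.r_max + 1e-12]

    @property
    def n_bins(self) -> int:
        return self.r_values.size

    @property
    def outer_radii(self) -> np.ndarray:
        return self.r_values + self.width

    def bin_of(self, r: float) -> int:
        """Index of the (first) annulus whose interval contains ``r``."""
        rv = self.r_values
        hit = (rv <= r) & (r < rv + self.width)
        idx = np.nonzero(hit)[0]
        if idx.size == 0:
            raise ValueError(f"r={r} falls in no annulus of this grid")
        return int(idx[0])

    def bins_of_distances(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (pair index, bin index) incidences for an array of distances.

        A distance may belong to several annuli when ``width > dr``; each
        incidence is returned once. Distances outside every annulus yield
        no incidence.
        """
        d = np.asarray(d, dtype=float)
        nb = self.n_bins
        # bins with r_k in (d - width, d]
        k_max = np.floor((d - self.r_start) / self.dr + 1e-12).astype(int)
        k_min = np.floor((d - self.width - self.r_start) / self.dr + 1e-12).astype(int) + 1
        k_min = np.maximum(k_min, 0)
        k_max = np.minimum(k_max, nb - 1)
        multiplicity = int(np.ceil(self.width / self.dr + 1e-12))
        pair_idx: list[np.ndarray] = []
        bin_idx: list[np.ndarray] = []
        for t in range(multiplicity):
            k = k_max - t
            ok = (k >= k_min) & (k >= 0)
            # half-open interval check guards floating fuzz at bin edges
            if ok.any():
                rk = self.r_start + self.dr * k[ok]
                dd = d[ok]
                good = (rk <= dd) & (dd < rk + self.width)
                sel = np.nonzero(ok)[0][good]
                pair_idx.append(sel)
                bin_idx.append(k[sel])
        if not pair_idx:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        return np.concatenate(pair_idx), np.concatenate(bin_idx)


@dataclass
class CorrelationCurve:
    """A correlation statistic evaluated on a radial grid.

    ``value[k]`` is the dimensionless observed/expected ratio on the
    annulus with inner radius ``r[k]``; 1 is the CSR reference level,
    values above 1 indicate clustering and below 1 exclusion. ``value``
    may contain NaN where the statistic is undefined (empty bins with
    zero expectation); it is never negative.
    """

    r: np.ndarray
    value: np.ndarray
    statistic: str = ""
    mark_a: object = None
    mark_b: object = None
    dr: float = float("nan")
    annulus_width: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.r.shape != self.value.shape:
            raise ValueError("r and value must have identical shapes")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r,
                "value": self.value,
                "statistic": self.statistic,
                "mark_a": str(self.mark_a),
                "mark_b": str(self.mark_b),
                "dr": self.dr,
                "annulus_width": self.annulus_width,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def mean_over(self, r_lo: float, r_hi: float) -> float:
        """Mean of the curve over inner radii in the closed range [r_lo, r_hi]."""
        sel = (self.r >= r_lo) & (self.r <= r_hi)
        return float(np.nanmean(self.value[sel]))
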