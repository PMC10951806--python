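"""Cell-table and raster IO, plus segmentation-free lattice sampling.

Cell tables are CSV files with one row per cell: x/y centroid
coordinates in μm, an optional categorical column (cell type) and any
number of continuous columns (stain intensities). The study domain is
either given explicitly or inferred as the tight bounding box of the
points.

``lattice_sample`` converts an intensity raster into a point pattern
without segmentation: one point per lattice node, carrying the local
pixel intensity as a continuous mark (and, optionally, a thresholded
positive/negative categorical mark). This enables wPCF analysis of
images for which no reliable cell segmentation exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pattern import Domain, PointPattern

__all__ = [
    "CellTableSchema",
    "read_cell_table",
    "write_cell_table",
    "read_raster",
    "lattice_sample",
]

log = logging.getLogger("spatcorr")


@dataclass(frozen=True)
class CellTableSchema:
    """Column mapping and (optional) explicit domain for a cell table."""

    x_column: str = "x"
    y_column: str = "y"
    categorical_column: str | None = "cell_type"
    continuous_columns: tuple[str, ...] = ()
    domain: Domain | None = None


def _bounding_domain(x: np.ndarray, y: np.ndarray) -> Domain:
    x_min, x_max = float(x.min()), float(x.max())
    y_min, y_max = float(y.min()), float(y.max())
    # degenerate extents (all points collinear) get a minimal positive size
    if x_min == x_max:
        x_max = x_min + 1.0
    if y_min == y_max:
        y_max = y_min + 1.0
    return Domain(x_min, x_max, y_min, y_max)


def read_cell_table(path, schema: CellTableSchema | None = None) -> PointPattern:
    """Read a cell-table CSV into a validated :class:`PointPattern`.

    Rows with coordinates outside an explicit domain are dropped (with a
    count in the log); with no explicit domain the tight bounding box is
    used. Missing columns raise a schema error naming the column;
    non-numeric coordinates raise a parse error naming the row.
    """
    if schema is None:
        schema = CellTableSchema()
    df = pd.read_csv(path)

    needed = [schema.x_column, schema.y_column]
    if schema.categorical_column is not None:
        needed.append(schema.categorical_column)
    needed.extend(schema.continuous_columns)
    for col in needed:
        if col not in df.columns:
            raise ValueError(
                f"schema column {col!r} not found in {path} "
                f"(columns: {', '.join(df.columns)})"
            )

    for col in (schema.x_column, schema.y_column):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"non-numeric coordinate in column {col!r} at row {row}")
        df[col] = vals

    x = df[schema.x_column].to_numpy(dtype=float)
    y = df[schema.y_column].to_numpy(dtype=float)

    if schema.domain is not None:
        domain = schema.domain
        inside = domain.contains(np.column_stack([x, y]))
        n_out = int((~inside).sum())
        if n_out:
            log.warning("dropping %d row(s) outside the explicit domain", n_out)
            df = df.loc[inside].reset_index(drop=True)
            x, y = x[inside], y[inside]
    else:
        domain = _bounding_domain(x, y)
        log.info("domain inferred as bounding box %s", domain)

    cat = None
    if schema.categorical_column is not None:
        cat = df[schema.categorical_column].astype(str).to_numpy(dtype=object)
    cont = {}
    for col in schema.continuous_columns:
        cont[col] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)

    return PointPattern(
        np.column_stack([x, y]), domain, categorical_marks=cat, continuous_marks=cont
    )


def write_cell_table(pattern: PointPattern, path, schema: CellTableSchema | None = None) -> None:
    """Write a pattern as a cell-table CSV (inverse of :func:`read_cell_table`)."""
    if schema is None:
        schema = CellTableSchema()
    df = pattern.to_dataframe(
        x_column=schema.x_column,
        y_column=schema.y_column,
        categorical_column=schema.categorical_column or "cell_type",
    )
    df.to_csv(path, index=False)


def read_raster(path) -> np.ndarray:
    """Read a single-band raster: TIFF by extension, else a text matrix."""
    spath = str(path)
    if spath.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = np.asarray(tifffile.imread(spath), dtype=float)
    else:
        arr = np.loadtxt(spath, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-band 2-D raster, got shape {arr.shape}")
    return arr


def lattice_sample(
    raster: np.ndarray,
    pixel_size: float,
    spacing: float = 20.0,
    threshold: float | None = None,
    intensity_column: str = "intensity",
) -> PointPattern:
    """Sample an intensity raster on a regular lattice of points.

    One point is placed at the center of each ``spacing`` x ``spacing``
    cell (offset spacing/2, so the lattice is symmetric under image
    flips), carrying the raster intensity at the nearest pixel as the
    continuous mark ``intensity``. With ``threshold`` given, each point
    also gets a categorical mark: 'positive' where intensity exceeds the
    threshold, else 'negative'. Raster row 0 is at the bottom of the
    domain (y increases with row index).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError(f"raster must be 2-D, got shape {raster.shape}")
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    if spacing < pixel_size:
        raise ValueError(
            f"lattice spacing ({spacing}) must be at least the pixel size ({pixel_size})"
        )

    ny, nx = raster.shape
    width = nx * pixel_size
    height = ny * pixel_size
    xs = np.arange(spacing / 2.0, width, spacing)
    ys = np.arange(spacing / 2.0, height, spacing)
    xx, yy = np.meshgrid(xs, ys)
    coords = np.column_stack([xx.ravel(), yy.ravel()])

    col = np.minimum((coords[:, 0] / pixel_size).astype(int), nx - 1)
    row = np.minimum((coords[:, 1] / pixel_size).astype(int), ny - 1)
    intensity = raster[row, col]

    cat = None
    if threshold is not None:
        cat = np.where(intensity > threshold, "positive", "negative").astype(object)

    return PointPattern(
        coords,
        Domain(0.0, width, 0.0, height),
        categorical_marks=cat,
        continuous_marks={intensity_column: intensity},
    )
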