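"""Regional aggregation, cumulative distributions and dose-rate gridding.

``grid_minimum_curvature`` interpolates scattered dose rates onto a regular
lon/lat grid as the classic minimum-curvature surface of geophysical
mapping: cells holding data are clamped and the free cells minimise the
discrete thin-plate bending energy, whose Euler-Lagrange equation is the
biharmonic equation away from the data.  The energy's null space is the
affine surfaces, so any plane through the data is reproduced exactly.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .types import DoseGrid

UNASSIGNED = "unassigned"
SD_SENTINEL = float("nan")  # printed as a dash in reports


# ---------------------------------------------------------------------------
# region assignment


def load_boundaries_geojson(path) -> list[tuple[str, BaseGeometry]]:
    """Read (region id, polygon) pairs from a GeoJSON FeatureCollection
    (WGS84, lon-lat order).  The region id is the feature's ``id`` or its
    ``name``/``region`` property."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for feature in doc.get("features", []):
        props = feature.get("properties") or {}
        rid = feature.get("id") or props.get("name") or props.get("region")
        if rid is None:
            raise ValueError("GeoJSON feature lacks an id/name/region")
        out.append((str(rid), shape(feature["geometry"])))
    return out


def assign_region(
    points: pd.DataFrame,
    boundaries: list[tuple[str, BaseGeometry]],
    tolerance: float = 0.1,
    lat_column: str = "lat",
    lon_column: str = "lon",
) -> pd.DataFrame:
    """Label points with the polygon containing them.

    Points outside every polygon are assigned to the nearest polygon within
    ``tolerance`` (degrees), else flagged ``unassigned``.
    """
    if not boundaries:
        raise ValueError("empty boundary set")
    labels = []
    for lat, lon in zip(points[lat_column], points[lon_column]):
        p = Point(lon, lat)
        label = None
        for rid, geom in boundaries:
            if geom.contains(p) or geom.touches(p):
                label = rid
                break
        if label is None:
            distances = [(geom.distance(p), rid) for rid, geom in boundaries]
            d, rid = min(distances)
            label = rid if d <= tolerance else UNASSIGNED
        labels.append(label)
    out = points.copy()
    out["region"] = labels
    return out


# ---------------------------------------------------------------------------
# summaries and distributions


def summarize(
    records: pd.DataFrame, value_column: str, group_column: str = "region"
) -> pd.DataFrame:
    """Per-group n, mean, sample SD, min and max.

    Groups with a single record carry the SD sentinel (NaN, printed as a
    dash), mirroring survey-table convention.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    if group_column not in records.columns:
        raise ValueError(f"missing group column: {group_column}")
    grouped = records.groupby(group_column, sort=True)[value_column]
    out = grouped.agg(n="count", mean="mean", sd="std", min="min", max="max")
    out.loc[out["n"] == 1, "sd"] = SD_SENTINEL
    return out.reset_index()


def cumulative_distribution(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and right-continuous fractions k/n."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    fractions = np.arange(1, v.size + 1) / v.size
    return v, fractions


def fraction_direct_below(direct, soil) -> float:
    """Fraction of paired sites whose direct value is strictly below the
    soil-derived one (the paired comparison behind the cumulative plots)."""
    d = np.asarray(direct, dtype=float)
    s = np.asarray(soil, dtype=float)
    if d.size == 0 or d.shape != s.shape:
        raise ValueError("paired input required")
    return float(np.mean(d < s))


# ---------------------------------------------------------------------------
# minimum-curvature gridding


def _curvature_operator(n_lat: int, n_lon: int):
    """Sparse stacked second-difference operator [Dyy; sqrt(2) Dxy; Dxx].

    ||A z||^2 is the discrete thin-plate bending energy
    sum (z_xx^2 + 2 z_xy^2 + z_yy^2); its null space is the affine surfaces
    a + b*lon + c*lat, so >= 3 non-collinear clamped data determine the
    minimum-curvature surface uniquely.
    """
    from scipy import sparse

    def second_diff(n):
        return sparse.diags_array(
            [1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(max(n - 2, 0), n)
        )

    def first_diff(n):
        return sparse.diags_array(
            [-1.0, 1.0], offsets=[0, 1], shape=(max(n - 1, 0), n)
        )

    eye_lat = sparse.eye_array(n_lat)
    eye_lon = sparse.eye_array(n_lon)
    d_yy = sparse.kron(second_diff(n_lat), eye_lon)
    d_xx = sparse.kron(eye_lat, second_diff(n_lon))
    d_xy = sparse.kron(first_diff(n_lat), first_diff(n_lon)) * np.sqrt(2.0)
    return sparse.vstack([d_yy, d_xy, d_xx]).tocsr()


def _solve_clamped_plate(
    data_mask: np.ndarray,
    data_values: np.ndarray,
    tolerance: float,
    max_iterations: int,
    method: str,
) -> np.ndarray:
    """Minimise the bending energy with data cells clamped.

    Solves the normal equations M z_free = -M z_data restricted to free
    cells (M = A^T A, SPD on the free cells once three non-collinear data
    cells exist), either by direct sparse factorisation (default) or by
    conjugate-gradient iteration stopping when the relative residual falls
    below ``tolerance``.
    """
    from scipy.sparse.linalg import cg, spsolve

    n_lat, n_lon = data_mask.shape
    free = (~data_mask).ravel()
    z0 = np.where(data_mask, data_values, 0.0).ravel()
    if not free.any():
        return z0.reshape(n_lat, n_lon)
    a = _curvature_operator(n_lat, n_lon)
    m = (a.T @ a).tocsr()
    rhs = -(m @ z0)[free]
    m_ff = m[free][:, free]
    if method == "direct":
        sol = spsolve(m_ff.tocsc(), rhs)
    elif method in ("cg", "iterative"):
        sol, info = cg(m_ff, rhs, rtol=tolerance, atol=0.0, maxiter=max_iterations)
        if info != 0:
            resid = np.linalg.norm(m_ff @ sol - rhs)
            raise RuntimeError(
                f"minimum-curvature iteration did not converge (cg info={info}); "
                f"residual norm {resid:.3g}"
            )
    else:
        raise ValueError("method must be 'direct' or 'cg'")
    z = z0.copy()
    z[free] = sol
    return z.reshape(n_lat, n_lon)


def grid_minimum_curvature(
    points: pd.DataFrame,
    spacing: float = 0.1,
    mask_radius_cells: int = 3,
    tolerance: float = 1e-10,
    max_iterations: int = 100_000,
    method: str = "direct",
    lat_column: str = "lat",
    lon_column: str = "lon",
    value_column: str = "dose_ngy_h",
    allow_degenerate: bool = False,
) -> DoseGrid:
    """Minimum-curvature surface through scattered data on a regular grid.

    Data are snapped to their nearest cell (multiple data in one cell are
    averaged) and clamped; the surface over the free cells minimises the
    discrete thin-plate bending energy, whose stationarity condition is the
    discrete biharmonic equation away from the data.  Linear fields are
    reproduced exactly.  ``method`` selects a direct sparse solve of the
    clamped system (default) or conjugate-gradient iteration on the same
    system.  Cells farther than ``mask_radius_cells`` (Chebyshev distance)
    from any datum cell are masked.
    """
    lats = np.asarray(points[lat_column], dtype=float)
    lons = np.asarray(points[lon_column], dtype=float)
    vals = np.asarray(points[value_column], dtype=float)
    if lats.size == 0:
        raise ValueError("no data points")
    if lats.size < 3 and not allow_degenerate:
        raise ValueError(
            "need >= 3 points for a non-degenerate surface (allow_degenerate to override)"
        )
    lon0, lon1 = lons.min(), lons.max()
    lat0, lat1 = lats.min(), lats.max()
    n_lon = max(int(np.ceil((lon1 - lon0) / spacing)) + 1, 1)
    n_lat = max(int(np.ceil((lat1 - lat0) / spacing)) + 1, 1)
    grid_lons = lon0 + spacing * np.arange(n_lon)
    grid_lats = lat0 + spacing * np.arange(n_lat)

    iy = np.clip(np.rint((lats - lat0) / spacing).astype(int), 0, n_lat - 1)
    ix = np.clip(np.rint((lons - lon0) / spacing).astype(int), 0, n_lon - 1)
    sums = np.zeros((n_lat, n_lon))
    counts = np.zeros((n_lat, n_lon))
    np.add.at(sums, (iy, ix), vals)
    np.add.at(counts, (iy, ix), 1.0)
    data_mask = counts > 0
    data_values = np.where(data_mask, sums / np.maximum(counts, 1), 0.0)

    if data_mask.sum() < 3:
        # degenerate constraint set: the zero-energy surface is constant
        z = np.full((n_lat, n_lon), float(np.mean(vals)))
        z[data_mask] = data_values[data_mask]
    else:
        z = _solve_clamped_plate(
            data_mask, data_values, tolerance, max_iterations, method
        )

    # Chebyshev distance transform to datum cells
    dist = np.full((n_lat, n_lon), np.inf)
    dy, dx = np.nonzero(data_mask)
    yy, xx = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    for cy, cx in zip(dy, dx):
        dist = np.minimum(dist, np.maximum(np.abs(yy - cy), np.abs(xx - cx)))
    mask = dist > mask_radius_cells
    return DoseGrid(grid_lons, grid_lats, z, mask, spacing)


def write_esri_ascii(grid: DoseGrid, path, nodata: float = -9999.0) -> None:
    """Write a dose grid as an ESRI ASCII raster (row order north to south)."""
    values = grid.masked_values()
    values = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcenter {grid.lons[0]:.6f}\n")
        fh.write(f"yllcenter {grid.lats[0]:.6f}\n")
        fh.write(f"cellsize {grid.spacing:.6f}\n")
        fh.write(f"nodata_value {nodata}\n")
        for row in values[::-1]:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")
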