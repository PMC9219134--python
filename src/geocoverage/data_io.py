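"""Cluster survey tables, covariate rasters and design matrices.

Survey data arrive as one row per sampling cluster: coordinates, survey
year, number of children examined (binomial trials n_j) and number
vaccinated (successes Y_j).  Environmental covariates arrive as gridded
single-band rasters; they are sampled at cluster locations by
nearest-cell lookup and assembled into a z-scored design matrix.

Rasters use the plain-text ESRI ASCII grid format so that the whole
pipeline is testable without binary dependencies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .projection import Projection

__all__ = [
    "ClusterRecord",
    "CovariateRaster",
    "CovariateMatrix",
    "SchemaError",
    "ValidationError",
    "read_clusters",
    "write_clusters",
    "read_ascii_grid",
    "write_ascii_grid",
    "extract_at_points",
    "build_design_matrix",
    "correlation_screen",
    "read_regions",
]

CLUSTER_COLUMNS = ["cluster_id", "lon", "lat", "year", "n_children", "n_vaccinated"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a data invariant (e.g. Y_j > n_j)."""


@dataclass
class ClusterRecord:
    """One surveyed location.

    ``n_children`` is the binomial denominator n_j, ``n_vaccinated`` the
    count of successes Y_j.  ``x``/``y`` are projected km coordinates.
    """

    cluster_id: str
    x: float
    y: float
    lon: float
    lat: float
    year: int
    n_children: int
    n_vaccinated: int
    region: str | None = None

    def __post_init__(self):
        if self.n_children < 0:
            raise ValidationError(f"cluster {self.cluster_id}: n_children < 0")
        if not (0 <= self.n_vaccinated <= self.n_children):
            raise ValidationError(
                f"cluster {self.cluster_id}: n_vaccinated={self.n_vaccinated} "
                f"outside [0, n_children={self.n_children}]"
            )


@dataclass
class CovariateRaster:
    """A gridded covariate surface on a regular km grid.

    ``values`` has shape (n_rows, n_cols) with row 0 the *northernmost*
    row (the ESRI ASCII convention); (origin_x, origin_y) is the
    lower-left corner of the extent in km.
    """

    name: str
    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-center coordinates, same shape as values."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        ys = ys[::-1]  # row 0 = north
        return np.meshgrid(xs, ys)


@dataclass
class CovariateMatrix:
    """Standardized design matrix X with its standardization constants."""

    columns: list[str]
    X: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    row_index: np.ndarray = field(default=None)  # indices of retained records
    n_dropped: int = 0

    def destandardize(self) -> np.ndarray:
        return self.X * self.sds + self.means

    def standardize_new(self, raw: np.ndarray) -> np.ndarray:
        """Apply the fit-time constants to new raw covariate values."""
        return (raw - self.means) / self.sds


# ---------------------------------------------------------------------------
# cluster tables


def read_clusters(path, projection: Projection | None = None) -> list[ClusterRecord]:
    """Read a cluster CSV/TSV and project lon/lat to km.

    Expected header: ``cluster_id,lon,lat,year,n_children,n_vaccinated[,region]``.
    When ``projection`` is None one is built about the centroid of the file's
    points.  If the table already carries projected ``x,y`` columns (as
    tables written by this package do) they are used verbatim.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"cluster_id": str})
    for col in CLUSTER_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "x" in df.columns and "y" in df.columns:
        x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
    else:
        if projection is None:
            projection = Projection.centered_on(df["lon"].to_numpy(), df["lat"].to_numpy())
        x, y = projection.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.n_vaccinated > row.n_children:
            raise ValidationError(
                f"row {i}: n_vaccinated={row.n_vaccinated} > n_children={row.n_children}"
            )
        records.append(
            ClusterRecord(
                cluster_id=str(row.cluster_id),
                x=float(x[i]),
                y=float(y[i]),
                lon=float(row.lon),
                lat=float(row.lat),
                year=int(row.year),
                n_children=int(row.n_children),
                n_vaccinated=int(row.n_vaccinated),
                region=str(row.region) if "region" in df.columns and not pd.isna(row.region) else None,
            )
        )
    return records


def write_clusters(records: Sequence[ClusterRecord], path) -> None:
    has_region = any(r.region is not None for r in records)
    cols = CLUSTER_COLUMNS + ["x", "y"] + (["region"] if has_region else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in records:
            row = [r.cluster_id, repr(r.lon), repr(r.lat), r.year,
                   r.n_children, r.n_vaccinated, repr(r.x), repr(r.y)]
            if has_region:
                row.append(r.region if r.region is not None else "")
            w.writerow(row)


def records_to_frame(records: Sequence[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in records],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "lon": [r.lon for r in records],
            "lat": [r.lat for r in records],
            "year": [r.year for r in records],
            "n_children": [r.n_children for r in records],
            "n_vaccinated": [r.n_vaccinated for r in records],
            "region": [r.region for r in records],
        }
    )


# ---------------------------------------------------------------------------
# rasters


def read_ascii_grid(path, name: str | None = None) -> CovariateRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", -9999.0)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape {values.shape} disagrees with header")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return CovariateRaster(
        name=name,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=nodata,
    )


def write_ascii_grid(raster: CovariateRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.origin_x)!r}\n")
        fh.write(f"yllcorner {float(raster.origin_y)!r}\n")
        fh.write(f"cellsize {float(raster.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata)!r}\n")
        vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _point_to_index(raster: CovariateRaster, x: np.ndarray, y: np.ndarray):
    """Nearest-cell indices; a point exactly on an interior cell boundary
    goes to the lower index."""
    u = (x - raster.origin_x) / raster.cell_size
    v = (y - raster.origin_y) / raster.cell_size
    col = np.floor(u).astype(int)
    row_bot = np.floor(v).astype(int)
    # boundary tie -> lower index (but the extent's own lower edge stays in cell 0)
    on_edge_u = (u == col) & (col > 0)
    on_edge_v = (v == row_bot) & (row_bot > 0)
    col = np.where(on_edge_u, col - 1, col)
    row_bot = np.where(on_edge_v, row_bot - 1, row_bot)
    inside = (col >= 0) & (col < raster.n_cols) & (row_bot >= 0) & (row_bot < raster.n_rows)
    row = raster.n_rows - 1 - row_bot  # row 0 = north
    return row, col, inside


def extract_at_points(raster: CovariateRaster, points: Iterable[tuple[float, float]]) -> np.ndarray:
    """Nearest-cell raster values at km points; NaN marks out-of-extent or
    nodata cells (missingness is a value, never an error)."""
    pts = np.atleast_2d(np.asarray(list(points), dtype=float))
    if pts.size == 0:
        return np.empty(0)
    row, col, inside = _point_to_index(raster, pts[:, 0], pts[:, 1])
    out = np.full(len(pts), np.nan)
    r, c = row[inside], col[inside]
    vals = raster.values[r, c]
    vals = np.where(vals == raster.nodata, np.nan, vals)
    out[inside] = vals
    return out


def read_regions(path) -> dict:
    """Read region polygons from GeoJSON: feature name → shapely geometry.

    The name is taken from the first of the ``name``/``NAME``/``region``
    properties (falling back to the feature index).
    """
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = {}
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        name = next((props[k] for k in ("name", "NAME", "region") if k in props), str(i))
        out[str(name)] = shape(feat["geometry"])
    return out


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(
    records: Sequence[ClusterRecord],
    rasters: Sequence[CovariateRaster],
    log1p_columns: Sequence[str] = (),
) -> CovariateMatrix:
    """Extract covariates at cluster points and z-score each column.

    Rows with any missing covariate are dropped (listwise deletion) and
    counted in ``n_dropped``.  ``log1p_columns`` names rasters (e.g. a
    population-density surface) given a log1p transform before scaling.
    """
    if not records or not rasters:
        raise ValueError("need at least one record and one raster")
    pts = [(r.x, r.y) for r in records]
    raw = np.column_stack([extract_at_points(rast, pts) for rast in rasters])
    names = [rast.name for rast in rasters]
    for j, nm in enumerate(names):
        if nm in log1p_columns:
            raw[:, j] = np.log1p(raw[:, j])
    keep = ~np.isnan(raw).any(axis=1)
    if not keep.any():
        raise ValueError("all rows dropped: every record has a missing covariate")
    kept = raw[keep]
    means = kept.mean(axis=0)
    sds = kept.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)  # constant column: leave centred
    X = (kept - means) / sds
    return CovariateMatrix(
        columns=list(names),
        X=X,
        means=means,
        sds=sds,
        row_index=np.flatnonzero(keep),
        n_dropped=int((~keep).sum()),
    )


def correlation_screen(
    cov: CovariateMatrix, threshold: float = 0.8
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson correlations with an advisory collinearity flag.

    For every pair with |r| ≥ threshold the *later* column in the input
    ordering is flagged; the retained list is returned but nothing is
    removed from downstream fits.  Constant columns yield NaN correlations
    and are never flagged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    X = cov.X
    if X.shape[1] < 2:
        raise ValueError("correlation screen needs at least two columns")
    sds = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    R[sds == 0, :] = np.nan
    R[:, sds == 0] = np.nan
    np.fill_diagonal(R, np.where(sds == 0, np.nan, 1.0))
    flagged: set[str] = set()
    z = X.shape[1]
    for i in range(z):
        for j in range(i + 1, z):
            r = R[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.add(cov.columns[j])
    retained = [c for c in cov.columns if c not in flagged]
    table = pd.DataFrame(R, index=cov.columns, columns=cov.columns)
    return retained, table
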