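"""Gridded spatiotemporal fields: masking, flattening, and sensor-list I/O.

A daily pollutant field on a regular grid is flattened to a dense
``n_cells x n_times`` matrix before decomposition.  Cells that are missing
(non-finite) at *any* time step are dropped from the geometry — the
decomposition needs complete rows — and the surviving cells keep a stable
row-major ordering so pivot indices are reproducible across runs.

Conventions (declared in every output header): 0-based ``(row, col)``
coordinates, row-major flattening, time index 0 = first snapshot.
``cell_id = row * n_cols + col`` on the *unmasked* grid, so ids survive
masking unchanged.  Units are metadata only; no conversion is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .placement import PlacementResult

__all__ = [
    "GridGeometry",
    "FieldMatrix",
    "field_from_cube",
    "load_field",
    "load_surface",
    "write_sensors",
    "write_field_netcdf",
]

#: Header comment prepended to every CSV artifact.
CSV_HEADER_NOTE = (
    "# coordinates: 0-based (row, col); row-major flattening; "
    "time index 0 = first snapshot\n"
)


@dataclass(frozen=True)
class GridGeometry:
    """Retained (unmasked) cells of a regular grid.

    ``cell_ids`` are row-major flat indices on the full grid, strictly
    increasing, so the mapping cell_id <-> (row, col) is bijective and
    masked cells appear nowhere.
    """

    n_rows: int
    n_cols: int
    cell_ids: np.ndarray
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.cell_ids, dtype=np.int64)
        object.__setattr__(self, "cell_ids", ids)
        if ids.ndim != 1 or ids.size == 0:
            raise ValueError("cell_ids must be a non-empty 1-D sequence")
        if len(np.unique(ids)) != ids.size:
            raise ValueError("cell_ids must be unique")
        if ids.min() < 0 or ids.max() >= self.n_rows * self.n_cols:
            raise ValueError("cell_id outside grid")
        if not np.all(np.diff(ids) > 0):
            raise ValueError("cell_ids must be sorted row-major (increasing)")
        for name in ("lon", "lat"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != ids.shape:
                    raise ValueError(f"{name} must align with cell_ids")

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    @property
    def rows(self) -> np.ndarray:
        """0-based grid row of each retained cell."""
        return self.cell_ids // self.n_cols

    @property
    def cols(self) -> np.ndarray:
        """0-based grid column of each retained cell."""
        return self.cell_ids % self.n_cols

    @property
    def has_coords(self) -> bool:
        return self.lon is not None and self.lat is not None

    def index_of(self, cell_ids) -> np.ndarray:
        """Positions of the given cell ids within this geometry's ordering."""
        pos = np.searchsorted(self.cell_ids, cell_ids)
        pos = np.atleast_1d(pos)
        wanted = np.atleast_1d(np.asarray(cell_ids))
        bad = (pos >= self.n_cells) | (self.cell_ids[np.minimum(pos, self.n_cells - 1)] != wanted)
        if np.any(bad):
            raise KeyError(f"cell ids not in geometry: {wanted[bad].tolist()}")
        return pos

    def unflatten(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-cell vector back onto the full (n_rows, n_cols) grid."""
        values = np.asarray(values)
        if values.shape[0] != self.n_cells:
            raise ValueError("values must align with cell_ids")
        grid = np.full((self.n_rows * self.n_cols,) + values.shape[1:], fill, dtype=float)
        grid[self.cell_ids] = values
        return grid.reshape((self.n_rows, self.n_cols) + values.shape[1:])


@dataclass
class FieldMatrix:
    """Masked gridded time series as a dense ``n_cells x n_times`` matrix.

    ``dt`` is the sampling interval in days (daily data: 1).  Concentration
    units (e.g. ug m^-3) are carried in ``units`` as metadata only.
    """

    X: np.ndarray
    geometry: GridGeometry
    dt: float = 1.0
    time_origin: str | None = None
    units: str = "ug m-3"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_cells x n_times)")
        if self.X.shape[0] != self.geometry.n_cells:
            raise ValueError("row count must equal number of retained cells")
        if self.X.shape[1] < 2:
            raise ValueError("need at least 2 time steps")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("field matrix contains non-finite entries")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_times(self) -> int:
        return self.X.shape[1]

    def window(self, start: int, end: int) -> np.ndarray:
        """View of snapshots ``start..end-1``."""
        return self.X[:, start:end]


def field_from_cube(
    cube: np.ndarray,
    dt: float = 1.0,
    time_origin: str | None = None,
    units: str = "ug m-3",
) -> FieldMatrix:
    """Build a :class:`FieldMatrix` from a ``(time, y, x)`` array.

    Any cell with a non-finite value at any time step is masked out.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise ValueError("cube must have dims (time, y, x)")
    n_t, n_rows, n_cols = cube.shape
    if n_t < 2:
        raise ValueError("need at least 2 time steps")
    flat = cube.reshape(n_t, n_rows * n_cols)  # row-major over (row, col)
    keep = np.all(np.isfinite(flat), axis=0)
    if not np.any(keep):
        raise ValueError("all cells masked (every cell has a missing value)")
    geometry = GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_ids=np.flatnonzero(keep))
    X = flat[:, keep].T.copy()
    return FieldMatrix(X=X, geometry=geometry, dt=dt, time_origin=time_origin, units=units)


def _infer_format(path: Path, fmt: str | None, choices: tuple[str, ...]) -> str:
    if fmt is not None:
        if fmt not in choices:
            raise ValueError(f"format must be one of {choices}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".nc", ".nc4", ".cdf"):
        return "netcdf" if "netcdf" in choices else choices[0]
    if suffix == ".csv":
        return "csv_long" if "csv_long" in choices else "csv"
    if suffix in (".json", ".geojson"):
        return "geojson"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def load_field(path, format: str | None = None) -> FieldMatrix:
    """Load a gridded daily field from NetCDF ``(time, y, x)`` or long CSV.

    The long CSV layout has columns ``cell_row, cell_col, time, value``;
    absent (row, col, time) combinations count as missing.  In either
    format, cells missing at any time step are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format, ("netcdf", "csv_long"))
    if fmt == "netcdf":
        import xarray as xr

        with xr.open_dataset(path) as ds:
            data_vars = [v for v in ds.data_vars if set(ds[v].dims) >= {"time", "y", "x"}]
            if not data_vars:
                raise ValueError("NetCDF file has no variable with dims (time, y, x)")
            da = ds[data_vars[0]].transpose("time", "y", "x")
            cube = da.values.astype(float)
            units = str(da.attrs.get("units", "ug m-3"))
            origin = None
            if "time" in ds.coords and ds["time"].size:
                origin = str(np.asarray(ds["time"].values).ravel()[0])
        return field_from_cube(cube, time_origin=origin, units=units)

    df = pd.read_csv(path, comment="#")
    required = {"cell_row", "cell_col", "time", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"long CSV needs columns {sorted(required)}")
    n_rows = int(df["cell_row"].max()) + 1
    n_cols = int(df["cell_col"].max()) + 1
    times = np.sort(df["time"].unique())
    if times.size < 2:
        raise ValueError("need at least 2 time steps")
    t_index = pd.Series(np.arange(times.size), index=times)
    cube = np.full((times.size, n_rows, n_cols), np.nan)
    cube[
        t_index[df["time"]].to_numpy(),
        df["cell_row"].to_numpy(),
        df["cell_col"].to_numpy(),
    ] = df["value"].to_numpy()
    return field_from_cube(cube, time_origin=str(times[0]))


def load_surface(path, geometry: GridGeometry) -> np.ndarray:
    """Load a per-cell surface (CSV ``cell_row, cell_col, value``) aligned to a geometry.

    Rows may come in any order; the result follows ``geometry.cell_ids``.
    Every unmasked cell must be present with a finite value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    required = {"cell_row", "cell_col", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"surface CSV needs columns {sorted(required)}")
    ids = df["cell_row"].to_numpy(dtype=np.int64) * geometry.n_cols + df["cell_col"].to_numpy(
        dtype=np.int64
    )
    lookup = pd.Series(df["value"].to_numpy(dtype=float), index=ids)
    if lookup.index.has_duplicates:
        raise ValueError("surface CSV has duplicate cells")
    missing = np.setdiff1d(geometry.cell_ids, lookup.index.to_numpy())
    if missing.size:
        raise ValueError(f"surface is missing {missing.size} unmasked cell(s), e.g. id {missing[0]}")
    values = lookup.reindex(geometry.cell_ids).to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError("surface has non-finite values on unmasked cells")
    return values


def write_surface_csv(values: np.ndarray, geometry: GridGeometry, path) -> None:
    """Write a per-cell surface as CSV ``cell_row, cell_col, value``."""
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.cell_ids.shape:
        raise ValueError("values must align with geometry.cell_ids")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(CSV_HEADER_NOTE)
        pd.DataFrame(
            {"cell_row": geometry.rows, "cell_col": geometry.cols, "value": values}
        ).to_csv(fh, index=False)


def write_field_netcdf(field: FieldMatrix, path) -> None:
    """Write a field as NetCDF ``(time, y, x)`` with masked cells as NaN."""
    import xarray as xr

    grid = field.geometry.unflatten(field.X)  # (n_rows, n_cols, n_times)
    cube = np.moveaxis(grid, -1, 0)
    ds = xr.Dataset(
        {"concentration": (("time", "y", "x"), cube, {"units": field.units})},
        coords={"time": np.arange(field.n_times) * field.dt},
        attrs={
            "conventions": "0-based (row, col); row-major flattening; time index 0 = first snapshot",
            "dt_days": field.dt,
            "time_origin": field.time_origin or "index 0",
        },
    )
    ds.to_netcdf(Path(path), engine="scipy")


def _sensor_table(placement: "PlacementResult", geometry: GridGeometry) -> pd.DataFrame:
    pos = geometry.index_of(placement.pivots)
    lon = geometry.lon[pos] if geometry.lon is not None else np.full(len(pos), np.nan)
    lat = geometry.lat[pos] if geometry.lat is not None else np.full(len(pos), np.nan)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(pos) + 1),
            "cell_id": np.asarray(placement.pivots),
            "row": geometry.rows[pos],
            "col": geometry.cols[pos],
            "lon": lon,
            "lat": lat,
            "residual_norm": placement.residual_norm,
            "eta": placement.eta,
            "score": placement.score,
        }
    )


def write_sensors(placement: "PlacementResult", geometry: GridGeometry, path, format: str | None = None) -> None:
    """Write an ordered sensor list as CSV or GeoJSON (RFC 7946).

    CSV columns: rank (1-based), cell_id, row, col, lon, lat (empty when
    the geometry has no coordinates), residual_norm, eta, score.  GeoJSON
    requires lon/lat and carries the same attributes as properties.
    """
    path = Path(path)
    fmt = _infer_format(path, format, ("csv", "geojson"))
    table = _sensor_table(placement, geometry)
    if fmt == "csv":
        with path.open("w") as fh:
            fh.write(CSV_HEADER_NOTE)
            table.to_csv(fh, index=False, float_format="%.10g")
        return
    if not geometry.has_coords:
        raise ValueError("GeoJSON output needs lon/lat in the geometry")
    features = []
    for rec in table.to_dict("records"):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [rec["lon"], rec["lat"]]},
                "properties": {
                    k: (int(rec[k]) if k in ("rank", "cell_id", "row", "col") else rec[k])
                    for k in ("rank", "cell_id", "row", "col", "residual_norm", "eta", "score")
                },
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_sensors_csv(path) -> pd.DataFrame:
    """Read back a sensor CSV written by :func:`write_sensors`."""
    return pd.read_csv(Path(path), comment="#")
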