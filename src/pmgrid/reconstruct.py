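"""Stage-4: apply the per-year Stage-3 forests to every grid cell and day.

Produces a complete (no missing cells or days), strictly positive
gridded PM2.5 series, supports periodic aggregation to mean fields, and
writes CF-style NetCDF or (Geo)TIFF output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec
from .stages import build_grid_stage3_table, predict_stage3
from .synthetic import SyntheticWorld

__all__ = ["GriddedSeries", "predict_grid", "aggregate", "write_grid", "read_grid"]


@dataclass
class GriddedSeries:
    """Reconstructed daily PM2.5 over the full grid.

    ``values`` is ``(n_days, ny, nx)`` in ug/m3; ``model_year`` records
    which per-year Stage-3 model produced each day.
    """

    grid: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray
    model_year: np.ndarray  # (n_days,) int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.dates), self.grid.ny, self.grid.nx):
            raise ValueError("values shape does not match grid/dates")

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV-style table (cell_id, date, pm25)."""
        T = len(self.dates)
        n = self.grid.n_cells
        return pd.DataFrame({
            "cell_id": np.tile(self.grid.cell_ids, T),
            "date": np.repeat(self.dates.to_numpy(), n),
            "pm25": self.values.reshape(T, n).ravel(),
        })


def predict_grid(
    models_by_year: dict,
    world: SyntheticWorld,
    aod_fields: dict,
    grid_lagged_by_year: dict,
    dates=None,
    chunk_days: int = 16,
) -> GriddedSeries:
    """Reconstruct PM2.5 at every cell for the requested dates.

    ``models_by_year`` maps year to a fitted Stage-3 model; every
    requested date's year must be covered. Predictor assembly reuses
    the Stage-3 grid table (lagged features from the all-donors grid
    variant), processed in day chunks to bound memory.
    """
    dates = world.dates if dates is None else pd.DatetimeIndex(dates)
    years = dates.year.to_numpy()
    missing_years = sorted(set(int(y) for y in years) - set(models_by_year))
    if missing_years:
        raise ValueError(f"no Stage-3 model for years {missing_years}")

    ny, nx = world.grid.ny, world.grid.nx
    out = np.empty((len(dates), ny, nx))
    cell_ids = world.grid.cell_ids
    for start in range(0, len(dates), chunk_days):
        chunk = dates[start:start + chunk_days]
        table = build_grid_stage3_table(
            world, cell_ids, chunk, aod_fields, grid_lagged_by_year
        )
        tyears = pd.to_datetime(table["date"]).dt.year.to_numpy()
        pred = np.empty(len(table))
        for y in np.unique(tyears):
            sel = tyears == y
            pred[sel] = predict_stage3(models_by_year[int(y)], table[sel])
        out[start:start + len(chunk)] = pred.reshape(len(chunk), ny, nx)
    return GriddedSeries(
        grid=world.grid, dates=dates, values=out, model_year=years.astype(int)
    )


def aggregate(series: GriddedSeries, period="annual"):
    """Per-cell arithmetic mean fields over a period.

    ``period="annual"`` returns ``{year: (ny, nx) field}`` using each
    calendar year's days present in the series; a sequence of dates
    returns the single mean field over exactly those days.
    """
    if isinstance(period, str):
        if period != "annual":
            raise ValueError(f"unknown period {period!r}")
        years = series.dates.year.to_numpy()
        return {
            int(y): series.values[years == y].mean(axis=0) for y in np.unique(years)
        }
    wanted = pd.DatetimeIndex(period)
    if len(wanted) == 0:
        raise ValueError("empty aggregation period")
    idx = series.dates.get_indexer(wanted)
    if (idx < 0).any():
        missing = wanted[idx < 0][0]
        raise ValueError(f"date {missing.date()} not in the series")
    return series.values[idx].mean(axis=0)


def _geotiff_tags(grid: GridSpec):
    """Minimal GeoTIFF georeferencing: pixel scale + top-left tiepoint."""
    top = grid.y0 + grid.ny * grid.cell_size
    scale = (float(grid.cell_size), float(grid.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(grid.x0), float(top), 0.0)
    return [
        (33550, "d", 3, scale, True),  # ModelPixelScaleTag
        (33922, "d", 6, tiepoint, True),  # ModelTiepointTag
    ]


def write_grid(obj, path, format: str = "netcdf", grid: GridSpec | None = None):
    """Write a :class:`GriddedSeries` or a single mean field to disk.

    ``format="netcdf"`` writes a CF-style file with dims (time, y, x)
    and a ``units`` attribute of ``ug m-3``; ``format="geotiff"``
    writes one band per day (or a single band for a 2-D field) with
    basic georeferencing tags. Values round-trip at float32 precision.
    """
    import tifffile
    import xarray as xr

    path = Path(path)
    fmt = format.lower()
    if isinstance(obj, GriddedSeries):
        values = obj.values
        dates = obj.dates
        grid = obj.grid
    else:
        values = np.asarray(obj)[None]
        dates = None
        if grid is None:
            raise ValueError("writing a bare field requires the grid")

    if fmt == "netcdf":
        coords = {
            "y": grid.y0 + (np.arange(grid.ny) + 0.5) * grid.cell_size,
            "x": grid.x0 + (np.arange(grid.nx) + 0.5) * grid.cell_size,
        }
        if dates is not None:
            coords["time"] = dates
            da = xr.DataArray(
                values.astype(np.float32), dims=("time", "y", "x"), coords=coords,
                name="pm25",
            )
        else:
            da = xr.DataArray(
                values[0].astype(np.float32), dims=("y", "x"), coords=coords, name="pm25"
            )
        da.attrs["units"] = "ug m-3"
        da.attrs["long_name"] = "reconstructed PM2.5 concentration"
        da.to_dataset().to_netcdf(path, engine="scipy")
    elif fmt == "geotiff":
        # Raster row 0 is the northernmost row, so flip the y axis.
        pages = values[:, ::-1, :].astype(np.float32)
        tifffile.imwrite(
            path, pages, photometric="minisblack", extratags=_geotiff_tags(grid)
        )
    else:
        raise ValueError(f"unknown format {format!r}; use 'netcdf' or 'geotiff'")
    return path


def read_grid(path, format: str = "netcdf") -> np.ndarray:
    """Read values written by :func:`write_grid` (bands/time first)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "netcdf":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            return ds["pm25"].values.copy()
    if fmt == "geotiff":
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return arr[:, ::-1, :]
    raise ValueError(f"unknown format {format!r}")
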