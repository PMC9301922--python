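"""Regular lat/lon rasters, station tables, QC and regridding.

All grids are regular latitude/longitude rasters with cell-center
coordinates and no map projection.  Cell intervals are treated as
``(edge_low, edge_high]`` on each axis, with the domain's minimum edge
included in the first cell, so a point lying exactly on an interior cell
boundary belongs to the lower/left cell.

Gridded stacks are read and written as CF-style NetCDF (classic format,
via the xarray/scipy backend); station data are CSV with the fixed header
``station_id,city_id,lat,lon,timestamp,value``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridSpec",
    "GridField",
    "QCConfig",
    "QCReport",
    "read_station_table",
    "daily_mean_from_hourly",
    "regrid_area_weighted",
    "sample_grid_at_stations",
]

STATION_COLUMNS = ("station_id", "city_id", "lat", "lon", "timestamp", "value")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon grid (degrees, cell-center convention)."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid extent is empty")
        for extent, name in (
            (self.lat_max - self.lat_min, "lat"),
            (self.lon_max - self.lon_min, "lon"),
        ):
            n = extent / self.resolution
            if abs(n - round(n)) > 1e-6:
                raise ValueError(f"{name} extent is not a multiple of the resolution")

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, ascending."""
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def lat_edges(self) -> np.ndarray:
        return self.lat_min + np.arange(self.n_lat + 1) * self.resolution

    def lon_edges(self) -> np.ndarray:
        return self.lon_min + np.arange(self.n_lon + 1) * self.resolution

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )

    def cell_index(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); boundary points go to the lower cell.

        Raises for points outside the domain box.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if not np.all(self.contains(lat, lon)):
            raise ValueError("coordinates outside the grid domain")
        i = np.ceil((lat - self.lat_min) / self.resolution).astype(int) - 1
        j = np.ceil((lon - self.lon_min) / self.resolution).astype(int) - 1
        return np.clip(i, 0, self.n_lat - 1), np.clip(j, 0, self.n_lon - 1)


@dataclass
class GridField:
    """A gridded daily stack: values + missing mask on a GridSpec.

    ``values`` has shape (n_dates, n_lat, n_lon); ``mask`` is True where the
    value is missing.  Values must be finite wherever the mask is False.
    """

    spec: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    units: str = ""
    name: str = "value"

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.dates), self.spec.n_lat, self.spec.n_lon)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != expected:
            raise ValueError("mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite values outside the missing mask")

    @property
    def coverage(self) -> float:
        """Fraction of unmasked cells over the whole stack."""
        return float(1.0 - self.mask.mean())

    def copy(self) -> "GridField":
        return GridField(
            spec=self.spec,
            dates=self.dates.copy(),
            values=self.values.copy(),
            mask=self.mask.copy(),
            units=self.units,
            name=self.name,
        )

    def to_dataset(self) -> xr.Dataset:
        vals = self.values.copy()
        vals[self.mask] = np.nan
        da = xr.DataArray(
            vals,
            dims=("time", "lat", "lon"),
            coords={"time": self.dates, "lat": self.spec.lats, "lon": self.spec.lons},
            name=self.name,
            attrs={"units": self.units},
        )
        ds = da.to_dataset()
        ds.attrs["resolution"] = self.spec.resolution
        ds["lat"].attrs["units"] = "degrees_north"
        ds["lon"].attrs["units"] = "degrees_east"
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, name: str | None = None) -> "GridField":
        if name is None:
            name = next(iter(ds.data_vars))
        da = ds[name]
        lats = np.asarray(da["lat"])
        lons = np.asarray(da["lon"])
        res = float(ds.attrs.get("resolution", np.median(np.diff(lats))))
        spec = GridSpec(
            lat_min=float(lats[0] - res / 2),
            lat_max=float(lats[-1] + res / 2),
            lon_min=float(lons[0] - res / 2),
            lon_max=float(lons[-1] + res / 2),
            resolution=res,
        )
        vals = np.asarray(da, dtype=float)
        return cls(
            spec=spec,
            dates=pd.DatetimeIndex(np.asarray(da["time"])),
            values=vals,
            mask=~np.isfinite(vals),
            units=str(da.attrs.get("units", "")),
            name=name,
        )

    @classmethod
    def from_netcdf(cls, path, name: str | None = None) -> "GridField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load(), name=name)


# ---------------------------------------------------------------------------
# Station QC and aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCConfig:
    """Hourly quality-control rules for surface monitors.

    ``value_min``/``value_max`` bound physically plausible hourly NO2
    (μg/m³); runs of ``stuck_run`` or more identical consecutive hourly
    values at one station are treated as a stuck instrument and dropped.
    """

    value_min: float = 0.0
    value_max: float = 500.0
    stuck_run: int = 6


@dataclass
class QCReport:
    n_input: int = 0
    n_nonfinite: int = 0
    n_out_of_range: int = 0
    n_stuck: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_nonfinite + self.n_out_of_range + self.n_stuck


def read_station_table(path, qc: QCConfig | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Read an hourly station CSV and apply QC.

    Returns the surviving hourly records (columns ``station_id, city_id,
    lat, lon, timestamp, value``) and a report counting dropped rows.
    Raises ``ValueError`` on a missing required column, and a dedicated
    signal (``EmptyTableError``) if nothing survives QC.
    """
    df = pd.read_csv(path)
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station table missing required columns: {sorted(missing)}")
    df = df.loc[:, list(STATION_COLUMNS)].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return apply_hourly_qc(df, qc)


class EmptyTableError(ValueError):
    """Raised when no record survives quality control."""


def apply_hourly_qc(df: pd.DataFrame, qc: QCConfig | None = None) -> tuple[pd.DataFrame, QCReport]:
    qc = qc or QCConfig()
    report = QCReport(n_input=len(df))

    finite = np.isfinite(df["value"].to_numpy(dtype=float))
    report.n_nonfinite = int((~finite).sum())
    df = df.loc[finite]

    in_range = (df["value"] >= qc.value_min) & (df["value"] <= qc.value_max)
    report.n_out_of_range = int((~in_range).sum())
    df = df.loc[in_range]

    # Stuck-instrument rule: per station, in time order, drop every member of
    # a run of >= stuck_run identical consecutive values.
    df = df.sort_values(["station_id", "timestamp"]).reset_index(drop=True)
    if len(df):
        new_run = (df["value"] != df["value"].shift()) | (
            df["station_id"] != df["station_id"].shift()
        )
        run_id = new_run.cumsum()
        run_len = run_id.map(run_id.value_counts())
        stuck = run_len >= qc.stuck_run
        report.n_stuck = int(stuck.sum())
        df = df.loc[~stuck].reset_index(drop=True)

    if not len(df):
        raise EmptyTableError("no station record survived quality control")
    return df, report


def daily_mean_from_hourly(hourly: pd.DataFrame, min_hours: int = 18) -> pd.DataFrame:
    """Aggregate QC-passed hourly records to station-day means.

    A station-day is kept only if at least ``min_hours`` valid hourly
    values are present (default 18, i.e. 75% of a day).  Output columns:
    ``station_id, city_id, lat, lon, date, value, n_hours``.
    """
    if not 1 <= min_hours <= 24:
        raise ValueError("min_hours must be in [1, 24]")
    df = hourly.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    grouped = df.groupby(["station_id", "date"], sort=True)
    daily = grouped.agg(
        city_id=("city_id", "first"),
        lat=("lat", "first"),
        lon=("lon", "first"),
        value=("value", "mean"),
        n_hours=("value", "size"),
    ).reset_index()
    daily = daily.loc[daily["n_hours"] >= min_hours].reset_index(drop=True)
    return daily[["station_id", "city_id", "lat", "lon", "date", "value", "n_hours"]]


# ---------------------------------------------------------------------------
# Area-weighted regridding
# ---------------------------------------------------------------------------


def _overlap_1d(dst_edges: np.ndarray, src_edges: np.ndarray) -> np.ndarray:
    """Pairwise interval-overlap lengths, shape (n_dst, n_src)."""
    lo = np.maximum(dst_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(dst_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid_area_weighted(src: GridField, dst: GridSpec) -> GridField:
    """Area-weighted mean of a GridField onto a destination GridSpec.

    Each destination cell is the overlap-area-weighted mean of the source
    cells it intersects; the area of an overlap fragment is
    Δlat·Δlon·cos(fragment mid-latitude).  Destination cells with no
    unmasked overlap are masked.  Because overlaps factorise on a regular
    lat/lon grid, the operation reduces to two 1-D overlap matrices.
    """
    s = src.spec
    if (
        dst.lat_min >= s.lat_max
        or dst.lat_max <= s.lat_min
        or dst.lon_min >= s.lon_max
        or dst.lon_max <= s.lon_min
    ):
        raise ValueError("source and destination domains are disjoint")

    lat_ov = _overlap_1d(dst.lat_edges(), s.lat_edges())
    # cos(latitude) area factor at the fragment mid-latitude
    lo = np.maximum(dst.lat_edges()[:-1, None], s.lat_edges()[None, :-1])
    hi = np.minimum(dst.lat_edges()[1:, None], s.lat_edges()[None, 1:])
    mid = np.where(lat_ov > 0, 0.5 * (lo + hi), 0.0)
    a = lat_ov * np.cos(np.deg2rad(mid))
    b = _overlap_1d(dst.lon_edges(), s.lon_edges())

    nt = len(src.dates)
    out = np.full((nt, dst.n_lat, dst.n_lon), np.nan)
    out_mask = np.ones((nt, dst.n_lat, dst.n_lon), dtype=bool)
    for t in range(nt):
        valid = ~src.mask[t]
        num = a @ np.where(valid, src.values[t], 0.0) @ b.T
        den = a @ valid.astype(float) @ b.T
        ok = den > 1e-15
        out[t][ok] = num[ok] / den[ok]
        out_mask[t] = ~ok
    return GridField(
        spec=dst, dates=src.dates, values=out, mask=out_mask, units=src.units, name=src.name
    )


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------


def sample_grid_at_stations(
    grids: Mapping[str, GridField] | Sequence[GridField],
    stations: pd.DataFrame,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Pair station-day records with grid values at the containing cell.

    ``grids`` is a mapping name -> GridField (or a sequence, using each
    field's ``name``); all must share a GridSpec and date axis.  Stations
    outside the domain are excluded with a warning.  Rows with any masked
    predictor are flagged ``incomplete`` (and dropped if requested).
    """
    if not isinstance(grids, Mapping):
        grids = {g.name: g for g in grids}
    fields = list(grids.values())
    spec = fields[0].spec
    dates = fields[0].dates
    for g in fields[1:]:
        if g.spec != spec or not g.dates.equals(dates):
            raise ValueError("all grids must share one GridSpec and date axis")

    df = stations.copy()
    inside = spec.contains(df["lat"].to_numpy(), df["lon"].to_numpy())
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} station-day records outside the grid domain were excluded"
        )
        df = df.loc[inside].reset_index(drop=True)

    date_pos = pd.Series(np.arange(len(dates)), index=dates)
    d = pd.to_datetime(df["date"]).dt.normalize()
    known = d.isin(date_pos.index)
    if not known.all():
        warnings.warn(f"{int((~known).sum())} records outside the grid date range were excluded")
        df = df.loc[known.to_numpy()].reset_index(drop=True)
        d = d.loc[known.to_numpy()]
    t = date_pos.loc[d].to_numpy()
    i, j = spec.cell_index(df["lat"].to_numpy(), df["lon"].to_numpy())

    incomplete = np.zeros(len(df), dtype=bool)
    for fname, g in grids.items():
        df[fname] = g.values[t, i, j]
        incomplete |= g.mask[t, i, j]
    df["incomplete"] = incomplete
    if drop_incomplete:
        df = df.loc[~df["incomplete"]].reset_index(drop=True)
    return df
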