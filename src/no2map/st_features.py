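"""Spatiotemporal weight features for tree models.

Air pollution is spatially and temporally autocorrelated, but plain
per-pixel tree models have no notion of "where" or "when" a sample sits.
These features encode that: the spatial term is latitude, longitude and
the square roots of inverse Haversine great-circle distances to nine
fixed domain anchors (four corners, four edge midpoints, the center);
the temporal term is the day of year and inverse day-distances to the
four mid-season days (spring equinox, summer solstice, autumn equinox,
winter solstice).  Small offsets (``delta_s`` km, ``delta_t`` days,
default 1) keep the inverse distances bounded at the anchors; a monotone
offset does not materially change where tree models split.

The concatenated vector has exactly 16 components.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "EARTH_RADIUS_KM",
    "SPATIAL_FEATURE_NAMES",
    "TEMPORAL_FEATURE_NAMES",
    "ST_FEATURE_NAMES",
    "haversine_km",
    "domain_anchors",
    "spatial_term",
    "temporal_term",
    "st_feature_frame",
]

EARTH_RADIUS_KM = 6371.0088

SPATIAL_FEATURE_NAMES = ["lat", "lon"] + [f"sw{i}" for i in range(1, 10)]
TEMPORAL_FEATURE_NAMES = ["doy"] + [f"tw{i}" for i in range(1, 5)]
ST_FEATURE_NAMES = SPATIAL_FEATURE_NAMES + TEMPORAL_FEATURE_NAMES

# Mid-season anchor days: (month, day) of the spring equinox, summer
# solstice, autumn equinox and winter solstice; day-of-year is re-derived
# per calendar year so leap years shift anchors correctly.
SEASON_ANCHOR_DATES = ((3, 21), (6, 21), (9, 22), (12, 22))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance (km) on a sphere of radius 6371.0088 km.

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def domain_anchors(spec: GridSpec) -> np.ndarray:
    """Nine (lat, lon) anchors of the study bounding box.

    Ordered top-left, top-middle, top-right, right-middle, bottom-right,
    bottom-middle, bottom-left, left-middle, center — i.e. clockwise from
    the north-west corner, then the center.
    """
    lat0, lat1 = spec.lat_min, spec.lat_max
    lon0, lon1 = spec.lon_min, spec.lon_max
    latm, lonm = 0.5 * (lat0 + lat1), 0.5 * (lon0 + lon1)
    return np.array(
        [
            (lat1, lon0),
            (lat1, lonm),
            (lat1, lon1),
            (latm, lon1),
            (lat0, lon1),
            (lat0, lonm),
            (lat0, lon0),
            (latm, lon0),
            (latm, lonm),
        ]
    )


def spatial_term(lat, lon, anchors: np.ndarray, delta_s: float = 1.0) -> np.ndarray:
    """Spatial weight vector(s): [lat, lon, sqrt(1/(D_1+δs)) .. sqrt(1/(D_9+δs))].

    ``anchors`` is the (9, 2) array from :func:`domain_anchors`; distances
    D_i are Haversine great-circle distances in km.  Output shape is
    ``(..., 11)``.
    """
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    d = haversine_km(
        lat[..., None], lon[..., None], anchors[:, 0], anchors[:, 1]
    )
    feats = np.sqrt(1.0 / (d + delta_s))
    return np.concatenate([lat[..., None], lon[..., None], feats], axis=-1)


def _season_anchor_doys(year: int) -> np.ndarray:
    return np.array(
        [_dt.date(year, m, d).timetuple().tm_yday for m, d in SEASON_ANCHOR_DATES], dtype=float
    )


def temporal_term(dates, delta_t: float = 1.0, mode: str = "cyclic") -> np.ndarray:
    """Temporal weight vector(s): [DOY, 1/(Dt_1+δt) .. 1/(Dt_4+δt)].

    Dt_i is the distance in days from the date to the i-th mid-season day
    of the same calendar year; in the default cyclic mode the distance
    wraps around the year end, ``min(|ΔDOY|, Y − |ΔDOY|)`` with Y the year
    length.  Output shape is ``(n, 5)`` (or ``(5,)`` for a scalar date).
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if mode not in ("cyclic", "linear"):
        raise ValueError("mode must be 'cyclic' or 'linear'")
    scalar = np.isscalar(dates) or isinstance(dates, (pd.Timestamp, _dt.date))
    idx = pd.DatetimeIndex([dates] if scalar else dates)
    doy = idx.dayofyear.to_numpy(dtype=float)
    years = idx.year.to_numpy()
    year_len = np.where(idx.is_leap_year, 366.0, 365.0)

    anchor_doys = np.empty((len(idx), 4))
    for y in np.unique(years):
        anchor_doys[years == y] = _season_anchor_doys(int(y))

    diff = np.abs(doy[:, None] - anchor_doys)
    if mode == "cyclic":
        diff = np.minimum(diff, year_len[:, None] - diff)
    feats = 1.0 / (diff + delta_t)
    out = np.concatenate([doy[:, None], feats], axis=1)
    return out[0] if scalar else out


def st_feature_frame(
    lat,
    lon,
    dates,
    spec: GridSpec,
    delta_s: float = 1.0,
    delta_t: float = 1.0,
    mode: str = "cyclic",
) -> pd.DataFrame:
    """Full 16-component spatiotemporal feature table for aligned samples.

    ``lat``, ``lon`` and ``dates`` must have equal length; one row is
    produced per sample, with columns :data:`ST_FEATURE_NAMES`.
    """
    anchors = domain_anchors(spec)
    sp = spatial_term(lat, lon, anchors, delta_s=delta_s)
    tp = temporal_term(dates, delta_t=delta_t, mode=mode)
    if sp.ndim == 1:
        sp = sp[None, :]
    if tp.ndim == 1:
        tp = tp[None, :]
    return pd.DataFrame(
        np.concatenate([sp, tp], axis=1), columns=ST_FEATURE_NAMES
    )
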