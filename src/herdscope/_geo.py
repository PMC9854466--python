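"""Spherical-earth geometry helpers.

All herd-scale distances (< a few km) are computed with the haversine
formula on a sphere of mean radius; the error versus an ellipsoid is
sub-metre at this scale, far below GPS noise.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

# Study-site reference used to anchor the planar simulation frame.
DEFAULT_REF_LAT = 28.72299
DEFAULT_REF_LON = 83.97360


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres. Accepts scalars or arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing in [0, 360) degrees; NaN for coincident points."""
    lat1r, lon1r, lat2r, lon2r = (np.radians(np.asarray(x, dtype=float))
                                  for x in (lat1, lon1, lat2, lon2))
    dlon = lon2r - lon1r
    x = np.sin(dlon) * np.cos(lat2r)
    y = np.cos(lat1r) * np.sin(lat2r) - np.sin(lat1r) * np.cos(lat2r) * np.cos(dlon)
    brg = np.degrees(np.arctan2(x, y)) % 360.0
    coincident = (np.asarray(lat1) == np.asarray(lat2)) & (np.asarray(lon1) == np.asarray(lon2))
    return np.where(coincident, np.nan, brg)


def planar_to_latlon(xy: np.ndarray, ref_lat: float = DEFAULT_REF_LAT,
                     ref_lon: float = DEFAULT_REF_LON) -> tuple[np.ndarray, np.ndarray]:
    """Convert local planar metres (x east, y north) to lat/lon degrees.

    Small-area equirectangular approximation around the reference point.
    """
    xy = np.asarray(xy, dtype=float)
    m_per_deg_lat = np.pi * EARTH_RADIUS_M / 180.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(ref_lat))
    lat = ref_lat + xy[..., 1] / m_per_deg_lat
    lon = ref_lon + xy[..., 0] / m_per_deg_lon
    return lat, lon


def latlon_to_planar(lat, lon, ref_lat: float = DEFAULT_REF_LAT,
                     ref_lon: float = DEFAULT_REF_LON) -> np.ndarray:
    """Inverse of :func:`planar_to_latlon` (same approximation)."""
    m_per_deg_lat = np.pi * EARTH_RADIUS_M / 180.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(ref_lat))
    x = (np.asarray(lon, dtype=float) - ref_lon) * m_per_deg_lon
    y = (np.asarray(lat, dtype=float) - ref_lat) * m_per_deg_lat
    return np.stack([x, y], axis=-1)
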