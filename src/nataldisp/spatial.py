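"""Great-circle geometry and breeder-density statistics.

All coordinates are WGS84 decimal degrees, latitude first.  Distances are
computed on a sphere of mean radius 6371.0088 km (haversine); at the scales
relevant for within-country natal dispersal (< 400 km) the difference from
ellipsoidal geodesics is below 0.3%.  An ellipsoidal mode is available via
``geodesic_km(..., ellipsoid=True)`` for users who need it.

Territory activity follows the field convention used in raptor monitoring:
a territory counts as active in a year if any of its (possibly several
alternative) nests shows an occupancy stage of at least 1, where stages are
ordinal 0-3 (0 none, 1 new nest material, 2 eggs/brood, 3 ringed nestlings).
The representative nest of a territory-year is the nest with the furthest
advanced stage, ties broken by smallest nest id.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "geodesic_km",
    "pairwise_km",
    "resolve_status",
    "buffer_density",
    "distance_to_border_km",
]


def _check_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinate")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValueError(f"latitude outside [-90, 90]: {lat}")
    if np.any(lon < -180.0) or np.any(lon > 180.0):
        raise ValueError(f"longitude outside [-180, 180]: {lon}")


def _haversine(lat1, lon1, lat2, lon2):
    """Vectorised haversine distance in km (inputs in degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_km(p, q, ellipsoid: bool = False) -> float:
    """Great-circle distance in km between two (lat, lon) points.

    Parameters
    ----------
    p, q : (lat, lon) pairs in decimal degrees.
    ellipsoid : if True, use a WGS84 ellipsoidal approximation
        (Lambert's formula on the mean-latitude reduced sphere) instead of
        the spherical haversine.
    """
    _check_latlon(p[0], p[1])
    _check_latlon(q[0], q[1])
    if ellipsoid:
        return _lambert_km(p, q)
    return float(_haversine(p[0], p[1], q[0], q[1]))


def _lambert_km(p, q) -> float:
    # WGS84 first-order ellipsoidal correction (Lambert 1942).
    a = 6378.137
    f = 1.0 / 298.257223563
    lat1, lon1 = math.radians(p[0]), math.radians(p[1])
    lat2, lon2 = math.radians(q[0]), math.radians(q[1])
    b1 = math.atan((1 - f) * math.tan(lat1))
    b2 = math.atan((1 - f) * math.tan(lat2))
    sigma = float(_haversine(math.degrees(math.atan(math.tan(b1))),
                             p[1],
                             math.degrees(math.atan(math.tan(b2))),
                             q[1])) / EARTH_RADIUS_KM
    if sigma == 0.0:
        return 0.0
    P = (b1 + b2) / 2.0
    Q = (b2 - b1) / 2.0
    X = (sigma - math.sin(sigma)) * (math.sin(P) ** 2 * math.cos(Q) ** 2) / math.cos(sigma / 2.0) ** 2
    Y = (sigma + math.sin(sigma)) * (math.cos(P) ** 2 * math.sin(Q) ** 2) / math.sin(sigma / 2.0) ** 2
    return a * (sigma - f / 2.0 * (X + Y))


def pairwise_km(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Distance matrix (km) between two arrays of (lat, lon) rows."""
    points_a = np.atleast_2d(np.asarray(points_a, dtype=float))
    points_b = np.atleast_2d(np.asarray(points_b, dtype=float))
    _check_latlon(points_a[:, 0], points_a[:, 1])
    _check_latlon(points_b[:, 0], points_b[:, 1])
    return _haversine(points_a[:, 0][:, None], points_a[:, 1][:, None],
                      points_b[None, :, 0], points_b[None, :, 1])


def resolve_status(nests: pd.DataFrame, year: int | None = None) -> pd.DataFrame:
    """Per-territory yearly activity and representative nest.

    Parameters
    ----------
    nests : one row per (territory_id, nest_id, year) with columns
        ``territory_id, nest_id, lat, lon, year, stage`` (stage ordinal 0-3).
    year : optionally restrict to one calendar year.

    Returns
    -------
    DataFrame with one row per (territory_id, year):
    ``territory_id, year, active, nest_id, lat, lon`` where ``nest_id`` is the
    representative nest (maximal stage, smallest nest id on ties).
    """
    required = {"territory_id", "nest_id", "lat", "lon", "year", "stage"}
    missing = required - set(nests.columns)
    if missing:
        raise ValueError(f"nest table missing columns: {sorted(missing)}")
    df = nests if year is None else nests[nests["year"] == year]
    if df.empty:
        return pd.DataFrame(columns=["territory_id", "year", "active", "nest_id", "lat", "lon"])
    # counts per territory-year must be >= 1 nest
    sizes = df.groupby(["territory_id", "year"]).size()
    if (sizes < 1).any():  # pragma: no cover - groupby cannot yield 0
        raise ValueError("territory-year with zero nests")
    # representative nest: max stage, ties -> smallest nest_id
    ordered = df.sort_values(["territory_id", "year", "stage", "nest_id"],
                             ascending=[True, True, False, True], kind="mergesort")
    rep = ordered.groupby(["territory_id", "year"], as_index=False).first()
    rep["active"] = rep["stage"] >= 1
    return rep[["territory_id", "year", "active", "nest_id", "lat", "lon"]].reset_index(drop=True)


def buffer_density(center, radius_km: float, year: int, statuses: pd.DataFrame,
                   exclude=None, inclusive: bool = True) -> int:
    """Number of active territories within ``radius_km`` of ``center``.

    Counts territories whose representative nest in ``year`` lies within the
    buffer.  The boundary is inclusive (<= radius) by default.  ``exclude``
    optionally removes one focal territory id from the count.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    _check_latlon(center[0], center[1])
    sub = statuses[(statuses["year"] == year) & statuses["active"]]
    if exclude is not None:
        sub = sub[sub["territory_id"] != exclude]
    if sub.empty:
        return 0
    d = _haversine(center[0], center[1], sub["lat"].to_numpy(), sub["lon"].to_numpy())
    return int(np.sum(d <= radius_km) if inclusive else np.sum(d < radius_km))


def _to_unit_vectors(lat, lon):
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1)


def distance_to_border_km(p, border: np.ndarray) -> float:
    """Minimum great-circle distance (km) from a point to a border polyline.

    The polyline is an ordered array of (lat, lon) vertices.  Per segment the
    cross-track distance to the great-circle arc is used when the point's
    projection falls inside the segment, otherwise the distance to the
    nearer endpoint.
    """
    border = np.atleast_2d(np.asarray(border, dtype=float))
    if border.shape[0] < 2:
        raise ValueError("border polyline needs at least 2 vertices")
    _check_latlon(p[0], p[1])
    _check_latlon(border[:, 0], border[:, 1])

    pv = _to_unit_vectors(p[0], p[1])            # (3,)
    vv = _to_unit_vectors(border[:, 0], border[:, 1])  # (m, 3)
    a, b = vv[:-1], vv[1:]                       # segment endpoints

    n = np.cross(a, b)                           # great-circle normals
    nn = np.linalg.norm(n, axis=1)
    best = np.inf
    # endpoint distances (covers degenerate zero-length segments too)
    vertex_ang = np.arccos(np.clip(vv @ pv, -1.0, 1.0))
    best = min(best, float(vertex_ang.min()) * EARTH_RADIUS_KM)

    ok = nn > 1e-15
    if np.any(ok):
        nhat = n[ok] / nn[ok][:, None]
        sin_xt = nhat @ pv                       # signed sine of cross-track angle
        # projection of p onto each great circle
        proj = pv[None, :] - sin_xt[:, None] * nhat
        pn = np.linalg.norm(proj, axis=1)
        good = pn > 1e-15
        if np.any(good):
            proj = proj[good] / pn[good][:, None]
            aa, bb = a[ok][good], b[ok][good]
            ang_ab = np.arccos(np.clip(np.sum(aa * bb, axis=1), -1.0, 1.0))
            ang_ap = np.arccos(np.clip(np.sum(aa * proj, axis=1), -1.0, 1.0))
            ang_pb = np.arccos(np.clip(np.sum(proj * bb, axis=1), -1.0, 1.0))
            within = np.abs(ang_ap + ang_pb - ang_ab) < 1e-9
            if np.any(within):
                xt = np.abs(np.arcsin(np.clip(sin_xt[good][within], -1.0, 1.0)))
                best = min(best, float(xt.min()) * EARTH_RADIUS_KM)
    return best
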