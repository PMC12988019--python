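"""Geodesic primitives on the WGS84 ellipsoid.

All distances and bearings in the package go through this module so that every
metric (nearest-neighbour distances, homing efficiency, trimming radii, join
and split rules) uses one consistent convention.  Distances are geodesic arc
lengths on the WGS84 ellipsoid, computed with a vectorised Vincenty inverse;
bearings are initial geodesic azimuths clockwise from true north.  A spherical
great-circle helper (mean radius 6 371.0088 km) is kept for cheap, guaranteed
lower/upper bounds used when pruning nearest-neighbour candidates.

At homing-flight scales (< 50 km) Vincenty agrees with Karney's algorithm
(e.g. geosphere::distGeo) to well below a millimetre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoPoint",
    "geodesic_distance_m",
    "initial_bearing_deg",
    "distance_m",
    "bearing_deg",
    "unit_xyz",
    "chord_to_arc_m",
    "EARTH_RADIUS_M",
    "WGS84_A",
    "WGS84_F",
]

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)

#: Mean earth radius (m); only used for spherical bounds, never for reported metrics.
EARTH_RADIUS_M = 6371008.8

# An ellipsoidal geodesic between two points with spherical (mean-radius)
# separation s is bounded within s * [1/SPHERE_BOUND, SPHERE_BOUND]: the local
# radius of curvature of WGS84 stays within ~0.56 % of the mean radius.
SPHERE_BOUND = 1.006


class UndefinedBearingError(ValueError):
    """Initial bearing requested between coincident points."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


try:  # compiled kernel: same algorithm, scalar loop, large speedup
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


def _vincenty_one(phi1, lam1, phi2, lam2, a, b, f, R):
    """One Vincenty inverse solution (radians in); returns (distance_m, az1_rad)."""
    U1 = np.arctan((1.0 - f) * np.tan(phi1))
    U2 = np.arctan((1.0 - f) * np.tan(phi2))
    L = lam2 - lam1
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    ok = False
    sin_sigma = 0.0
    cos_sigma = 1.0
    sigma = 0.0
    cos2_alpha = 1.0
    cos_2sm = 1.0
    sin_lam = 0.0
    cos_lam = 1.0
    for _ in range(50):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        sin_sigma = np.sqrt(t1 * t1 + t2 * t2)
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        if sin_sigma > 0.0:
            sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        else:
            sin_alpha = 0.0
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha > 0.0:
            cos_2sm = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        else:
            cos_2sm = 0.0
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_new = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1.0 + 2.0 * cos_2sm * cos_2sm))
        )
        delta = abs(lam_new - lam)
        lam = lam_new
        if delta < 1e-12:
            ok = True
            break
    az = np.arctan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    if sin_sigma == 0.0:
        return 0.0, 0.0
    if not ok:
        # nearly antipodal: spherical fallback (out of scope distances)
        h = (
            np.sin((phi2 - phi1) / 2.0) ** 2
            + np.cos(phi1) * np.cos(phi2) * np.sin(L / 2.0) ** 2
        )
        return 2.0 * R * np.arcsin(min(1.0, np.sqrt(h))), az
    u2 = cos2_alpha * (a * a - b * b) / (b * b)
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    d_sigma = (
        B
        * sin_sigma
        * (
            cos_2sm
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sm * cos_2sm)
                - B
                / 6.0
                * cos_2sm
                * (-3.0 + 4.0 * sin_sigma * sin_sigma)
                * (-3.0 + 4.0 * cos_2sm * cos_2sm)
            )
        )
    )
    return b * A * (sigma - d_sigma), az


def _vincenty_array_kernel(phi1, lam1, phi2, lam2, dist, az, a, b, f, R):
    for i in range(phi1.size):
        dist[i], az[i] = _vincenty_one(phi1[i], lam1[i], phi2[i], lam2[i], a, b, f, R)


if _HAVE_NUMBA:
    _vincenty_one = _njit(cache=True, inline="always")(_vincenty_one)
    _vincenty_array_kernel = _njit(cache=True)(_vincenty_array_kernel)


def _vincenty_compiled(lat1, lon1, lat2, lon2):
    args = [np.asarray(x, dtype=np.float64) for x in (lat1, lon1, lat2, lon2)]
    if not (args[0].shape == args[1].shape == args[2].shape == args[3].shape):
        args = np.broadcast_arrays(*args)
    shape = args[0].shape
    rad = [np.radians(x).ravel() for x in args]
    dist = np.empty(rad[0].size)
    az = np.empty(rad[0].size)
    _vincenty_array_kernel(*rad, dist, az, WGS84_A, WGS84_B, WGS84_F, EARTH_RADIUS_M)
    return dist.reshape(shape), az.reshape(shape)


def _vincenty_numpy(lat1, lon1, lat2, lon2, tol: float = 1e-12, maxiter: int = 50):
    """Vectorised Vincenty inverse; returns (distance_m, azimuth1_rad).

    Falls back to the spherical great-circle for the (nearly antipodal)
    elements that fail to converge -- unreachable at homing-flight scales.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=np.float64) for a in (lat1, lon1, lat2, lon2))
    )
    phi1, lam1, phi2, lam2 = (np.radians(a) for a in (lat1, lon1, lat2, lon2))
    f = WGS84_F
    U1 = np.arctan((1.0 - f) * np.tan(phi1))
    U2 = np.arctan((1.0 - f) * np.tan(phi2))
    L = lam2 - lam1
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    converged = np.zeros(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos2_alpha = np.ones_like(lam)
    cos_2sm = np.ones_like(lam)
    sin_lam = np.zeros_like(lam)
    cos_lam = np.ones_like(lam)

    for _ in range(maxiter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_alpha = np.where(sin_sigma > 0, cosU1 * cosU2 * sin_lam / sin_sigma, 0.0)
        cos2_alpha = 1.0 - sin_alpha**2
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_2sm = np.where(
                cos2_alpha > 0, cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha, 0.0
            )
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_new = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        delta = np.abs(lam_new - lam)
        lam = lam_new
        converged = delta < tol
        if converged.all():
            break

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    d_sigma = (
        B
        * sin_sigma
        * (
            cos_2sm
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
                - B
                / 6.0
                * cos_2sm
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sm**2)
            )
        )
    )
    dist = WGS84_B * A * (sigma - d_sigma)
    dist = np.where(sin_sigma == 0.0, 0.0, dist)

    if not converged.all():
        bad = ~converged
        dist = np.where(bad, _haversine_m(lat1, lon1, lat2, lon2), dist)

    az1 = np.arctan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    return dist, az1


#: Active inverse-geodesic routine: the compiled kernel when numba is
#: importable (it is a declared dependency), the numpy path otherwise.  Both
#: implement the identical algorithm; tests assert their agreement.
_vincenty = _vincenty_compiled if _HAVE_NUMBA else _vincenty_numpy


def _haversine_m(lat1, lon1, lat2, lon2):
    """Spherical great-circle distance, mean radius; bounds helper only."""
    phi1, lam1, phi2, lam2 = (
        np.radians(np.asarray(a, dtype=np.float64)) for a in (lat1, lon1, lat2, lon2)
    )
    h = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def within_m(lats, lons, lat0, lon0, radius_m: float) -> np.ndarray:
    """Elementwise test ``geodesic_distance <= radius_m``, cheaply.

    Spherical distances bound the ellipsoidal geodesic within a factor
    SPHERE_BOUND, so only points inside the narrow ambiguity band around the
    radius need the exact Vincenty evaluation.  Decisions are identical to
    thresholding :func:`distance_m` directly.
    """
    lats = np.asarray(lats, dtype=np.float64)
    lons = np.asarray(lons, dtype=np.float64)
    h = _haversine_m(lats, lons, lat0, lon0)
    out = h * SPHERE_BOUND <= radius_m  # certainly inside
    ambiguous = ~out & (h / SPHERE_BOUND <= radius_m)
    if ambiguous.any():
        idx = np.flatnonzero(ambiguous)
        out[idx] = distance_m(lats[idx], lons[idx], lat0, lon0) <= radius_m
    return out


def distance_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Elementwise WGS84 geodesic distance (m); broadcasts like numpy."""
    dist, _ = _vincenty(lat1, lon1, lat2, lon2)
    return dist


def bearing_deg(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Elementwise initial geodesic bearing (degrees in [0, 360))."""
    _, az1 = _vincenty(lat1, lon1, lat2, lon2)
    return np.degrees(az1) % 360.0


def geodesic_distance_m(p: GeoPoint, q: GeoPoint) -> float:
    """WGS84 geodesic distance between two points, in metres."""
    return float(distance_m(p.lat, p.lon, q.lat, q.lon))


def initial_bearing_deg(p: GeoPoint, q: GeoPoint) -> float:
    """Initial geodesic bearing from ``p`` to ``q``, clockwise from true north.

    Raises
    ------
    UndefinedBearingError
        If the two points coincide.
    """
    if p.lat == q.lat and p.lon == q.lon:
        raise UndefinedBearingError("bearing undefined for coincident points")
    return float(bearing_deg(p.lat, p.lon, q.lat, q.lon))


def unit_xyz(lats, lons) -> np.ndarray:
    """Map lat/lon arrays to 3-D points on a sphere of mean earth radius.

    Euclidean (chord) distance on this embedding is monotone in spherical
    great-circle distance, so KD-tree nearest-neighbour queries on it rank
    points exactly as the great-circle metric does.
    """
    phi = np.radians(np.asarray(lats, dtype=np.float64))
    lam = np.radians(np.asarray(lons, dtype=np.float64))
    cp = np.cos(phi)
    return EARTH_RADIUS_M * np.column_stack(
        (cp * np.cos(lam), cp * np.sin(lam), np.sin(phi))
    )


def chord_to_arc_m(chord) -> np.ndarray:
    """Convert chord lengths from :func:`unit_xyz` space to great-circle metres."""
    x = np.asarray(chord, dtype=np.float64) / (2.0 * EARTH_RADIUS_M)
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, x))
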