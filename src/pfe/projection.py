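"""Transverse Mercator (UTM) projection on the WGS84 ellipsoid.

Forward and inverse mappings use the Krüger series in the third
flattening ``n`` carried to order ``n^3``, which keeps round-trip error
well below a metre anywhere inside a UTM zone — ample for kilometre-scale
grid work.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_E0 = 500_000.0  # false easting, m

_N = _F / (2.0 - _F)
# rectifying radius
_RA = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0)

_ALPHA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 5.0 * _N**3 / 16.0,
    13.0 * _N**2 / 48.0 - 3.0 * _N**3 / 5.0,
    61.0 * _N**3 / 240.0,
)
_BETA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 37.0 * _N**3 / 96.0,
    _N**2 / 48.0 + _N**3 / 15.0,
    17.0 * _N**3 / 480.0,
)
_DELTA = (
    2.0 * _N - 2.0 * _N**2 / 3.0 - 2.0 * _N**3,
    7.0 * _N**2 / 3.0 - 8.0 * _N**3 / 5.0,
    56.0 * _N**3 / 15.0,
)


def utm_zone_from_lon(lon: float) -> int:
    """UTM zone number (1-60) containing longitude ``lon`` in degrees."""
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    return min(int(math.floor((lon + 180.0) / 6.0)) + 1, 60)


def zone_central_meridian(zone: int) -> float:
    """Central meridian (degrees) of a UTM zone."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone {zone} outside 1-60")
    return -183.0 + 6.0 * zone


def geographic_to_utm(
    lon: Iterable[float] | float,
    lat: Iterable[float] | float,
    zone: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to UTM easting/northing (metres).

    Northern-hemisphere convention (no 10,000 km false northing):
    southern latitudes get negative northings, which keeps a study area
    straddling the equator continuous.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam0 = math.radians(zone_central_meridian(zone))
    dlam = np.radians(lon) - lam0
    if np.any(np.abs(np.degrees(dlam)) > 9.0):
        warnings.warn(
            f"coordinates more than 9 deg from zone {zone} central meridian; "
            "distortion grows away from the zone",
            stacklevel=2,
        )
    phi = np.radians(lat)

    two_sqrt_n = 2.0 * math.sqrt(_N) / (1.0 + _N)
    t = np.sinh(np.arctanh(np.sin(phi)) - two_sqrt_n * np.arctanh(two_sqrt_n * np.sin(phi)))
    xi_p = np.arctan2(t, np.cos(dlam))
    eta_p = np.arctanh(np.sin(dlam) / np.sqrt(1.0 + t**2))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta += a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _E0 + _K0 * _RA * eta
    northing = _K0 * _RA * xi
    return easting, northing


def utm_to_geographic(
    easting: Iterable[float] | float,
    northing: Iterable[float] | float,
    zone: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`geographic_to_utm`; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = northing / (_K0 * _RA)
    eta = (easting - _E0) / (_K0 * _RA)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p -= b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p -= b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    phi = chi.copy()
    for j, d in enumerate(_DELTA, start=1):
        phi += d * np.sin(2 * j * chi)

    lam0 = math.radians(zone_central_meridian(zone))
    lam = lam0 + np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    return np.degrees(lam), np.degrees(phi)
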