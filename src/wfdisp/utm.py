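"""Transverse Mercator (UTM zone 30N) forward and inverse projection.

Survey positions are logged as WGS84 longitude/latitude but all modelling is
done on a planar easting/northing grid, so segment lengths and knot distances
are metric.  The projection is the standard UTM mapping (scale factor 0.9996,
false easting 500 km) evaluated with the Krüger series carried to sixth order
in the third flattening, which is accurate to well below a millimetre over the
zone's validity band.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0

ZONE30_LON0 = -3.0  # central meridian of UTM zone 30, degrees

_N = _F / (2.0 - _F)  # third flattening
_E2 = _F * (2.0 - _F)  # first eccentricity squared
_E = np.sqrt(_E2)

# rectifying radius
_ABAR = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Krüger alpha (forward) and beta (inverse) coefficients, order n^6
_ALPHA = np.array(
    [
        _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
        - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
        13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440
        + 281 * _N**5 / 630 - 1983433 * _N**6 / 1935360,
        61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
        + 167603 * _N**6 / 181440,
        49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
        34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
        212378941 * _N**6 / 319334400,
    ]
)
_BETA = np.array(
    [
        _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
        - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
        _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
        - 1118711 * _N**6 / 3870720,
        17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
        + 5569 * _N**6 / 90720,
        4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
        4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
        20648693 * _N**6 / 638668800,
    ]
)

_J = np.arange(1, 7)


def project_to_utm(lon, lat, lon0: float = ZONE30_LON0):
    """Project WGS84 longitude/latitude (degrees) to UTM easting/northing (m).

    Parameters
    ----------
    lon, lat : array_like
        Coordinates in decimal degrees.  Must lie within the zone's validity
        band: latitude in (-84, 84) and longitude within 7 degrees of the
        central meridian (zone width plus a small buffer).
    lon0 : float
        Central meridian in degrees; defaults to zone 30 (3 degrees W).

    Returns
    -------
    (easting, northing) : ndarray pair in metres (northern-hemisphere datum,
    false northing 0).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) >= 84.0):
        raise ValueError("latitude outside transverse-Mercator validity band (|lat| < 84)")
    if np.any(np.abs(lon - lon0) > 7.0):
        raise ValueError(
            f"longitude more than 7 degrees from central meridian {lon0}; wrong UTM zone?"
        )
    phi = np.radians(lat)
    lam = np.radians(lon - lon0)

    sphi = np.sin(phi)
    t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.sqrt(t**2 + np.cos(lam) ** 2))

    jxi = 2.0 * np.multiply.outer(xi_p, _J)
    jeta = 2.0 * np.multiply.outer(eta_p, _J)
    xi = xi_p + np.sum(_ALPHA * np.sin(jxi) * np.cosh(jeta), axis=-1)
    eta = eta_p + np.sum(_ALPHA * np.cos(jxi) * np.sinh(jeta), axis=-1)

    easting = _FALSE_EASTING + _K0 * _ABAR * eta
    northing = _K0 * _ABAR * xi
    return easting, northing


def utm_to_lonlat(easting, northing, lon0: float = ZONE30_LON0):
    """Inverse of :func:`project_to_utm`; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = northing / (_K0 * _ABAR)
    eta = (easting - _FALSE_EASTING) / (_K0 * _ABAR)

    jxi = 2.0 * np.multiply.outer(xi, _J)
    jeta = 2.0 * np.multiply.outer(eta, _J)
    xi_p = xi - np.sum(_BETA * np.sin(jxi) * np.cosh(jeta), axis=-1)
    eta_p = eta - np.sum(_BETA * np.cos(jxi) * np.sinh(jeta), axis=-1)

    t = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # invert the conformal-latitude relation tau' -> phi by fixed point:
    # tan(phi) = sinh(psi + e * atanh(e * sin(phi))), psi = asinh(tau')
    psi = np.arcsinh(t)
    phi = np.arctan(t)
    for _ in range(10):
        phi = np.arctan(np.sinh(psi + _E * np.arctanh(_E * np.sin(phi))))

    return np.degrees(lam) + lon0, np.degrees(phi)
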