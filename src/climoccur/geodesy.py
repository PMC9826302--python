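"""Geodesic helpers on the WGS84 ellipsoid / authalic sphere.

Distances use the haversine formula on the authalic sphere (adequate at the
10-km scale of the coastal filter). Polygon areas convert geodetic latitude
to authalic latitude and evaluate the exact spherical excess on the authalic
sphere, which preserves ellipsoidal areas to well under 0.1% for the
convex-hull sizes that occur in range estimation.
"""

from __future__ import annotations

import numpy as np

WGS84_A_KM = 6378.137
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)

# radius of the sphere with the same surface area as the WGS84 ellipsoid
AUTHALIC_RADIUS_KM = 6371.0071809


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; accepts scalars or numpy arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * AUTHALIC_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def authalic_latitude(lat_deg):
    """Convert geodetic latitude (degrees) to authalic latitude (radians)."""
    e = np.sqrt(WGS84_E2)
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    s = np.sin(phi)

    def q(sinphi):
        return (1.0 - WGS84_E2) * (
            sinphi / (1.0 - WGS84_E2 * sinphi ** 2)
            - (1.0 / (2.0 * e)) * np.log((1.0 - e * sinphi) / (1.0 + e * sinphi))
        )

    qp = q(1.0)
    return np.arcsin(np.clip(q(s) / qp, -1.0, 1.0))


def _unit_vectors(lons_deg, lats_auth_rad):
    lam = np.radians(np.asarray(lons_deg, dtype=float))
    phi = np.asarray(lats_auth_rad, dtype=float)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def _triangle_excess(a, b, c):
    """Spherical excess of triangle with unit-vector vertices (l'Huilier), signed."""
    def side(u, v):
        return np.arctan2(np.linalg.norm(np.cross(u, v)), float(np.dot(u, v)))

    sa, sb, sc = side(b, c), side(c, a), side(a, b)
    s = 0.5 * (sa + sb + sc)
    t = (np.tan(s / 2.0) * np.tan((s - sa) / 2.0)
         * np.tan((s - sb) / 2.0) * np.tan((s - sc) / 2.0))
    excess = 4.0 * np.arctan(np.sqrt(max(t, 0.0)))
    sign = np.sign(np.dot(a, np.cross(b, c)))
    return sign * excess


def polygon_area_km2(lons, lats):
    """Area of a lon/lat polygon (vertices in order, not closed) in km².

    Evaluated as the spherical excess on the authalic sphere after converting
    to authalic latitude; a close approximation to the geodesic area on the
    WGS84 ellipsoid.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if len(lons) < 3:
        return 0.0
    v = _unit_vectors(lons, authalic_latitude(lats))
    total = 0.0
    for i in range(1, len(v) - 1):
        total += _triangle_excess(v[0], v[i], v[i + 1])
    return abs(total) * AUTHALIC_RADIUS_KM ** 2


def equal_area_xy(lon, lat):
    """Lambert cylindrical equal-area projection (std parallel 0°), km.

    Used to lay the fixed-origin square grid for area-of-occupancy counts;
    equal-area by construction on the authalic sphere.
    """
    lon = np.asarray(lon, dtype=float)
    x = AUTHALIC_RADIUS_KM * np.radians(lon)
    y = AUTHALIC_RADIUS_KM * np.sin(authalic_latitude(lat))
    return x, y
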