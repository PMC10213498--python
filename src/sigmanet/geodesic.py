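"""WGS84 geodesic distance (Vincenty's inverse method).

Used for sampling widths of empirical lat/lon data.  Accurate to well under
a metre for the sub-1000 km scales this package targets; may fail to
converge only for nearly antipodal points, which raises rather than
returning a silently wrong distance.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0            # semi-major axis, m
_F = 1.0 / 298.257223563  # flattening
_B = _A * (1.0 - _F)


def geodesic_km(lat1: float, lon1: float, lat2: float, lon2: float,
                tol: float = 1e-12, max_iter: int = 200) -> float:
    """Geodesic distance between two (lat, lon) points in kilometres."""
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - _F) * np.tan(phi1))
    U2 = np.arctan((1 - _F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * _F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sigma_m
                                     + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)))
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ValueError("geodesic iteration failed to converge (near-antipodal points)")

    u2 = cos2_alpha * (_A**2 - _B**2) / _B**2
    Acoef = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    Bcoef = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = Bcoef * sin_sigma * (
        cos_2sigma_m + Bcoef / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
            - Bcoef / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma**2)
            * (-3.0 + 4.0 * cos_2sigma_m**2)))
    return float(_B * Acoef * (sigma - delta_sigma)) / 1000.0
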