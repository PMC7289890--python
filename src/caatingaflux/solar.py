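"""Solar geometry for half-hourly tower records.

Only what the generator and the nighttime flag need: solar declination,
elevation angle and a clear-sky shortwave estimate.  Local standard time
(no DST) is assumed throughout; hour angle is computed from clock time,
i.e. solar noon is taken at 12:00 local.
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 1361.0  # W m-2


def declination(doy: np.ndarray | float) -> np.ndarray | float:
    """Solar declination (radians) for day-of-year via the Cooper formula."""
    return np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (np.asarray(doy) + 10.0) / 365.25)


def sin_elevation(lat_deg: float, doy, hour_local) -> np.ndarray:
    """Sine of solar elevation at local clock time ``hour_local`` (decimal hours)."""
    lat = np.deg2rad(lat_deg)
    dec = declination(doy)
    ha = np.deg2rad(15.0 * (np.asarray(hour_local, dtype=float) - 12.0))
    s = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha)
    return np.asarray(s)


def clear_sky_rg(lat_deg: float, doy, hour_local, transmissivity: float = 0.75) -> np.ndarray:
    """Clear-sky global radiation (W m-2); zero when the sun is below the horizon."""
    s = sin_elevation(lat_deg, doy, hour_local)
    return np.where(s > 0.0, SOLAR_CONSTANT * transmissivity * s, 0.0)
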