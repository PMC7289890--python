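"""Turbulent CO2 flux, storage term and NEE assembly.

The half-hourly net ecosystem exchange is the sum of the turbulent flux
through the measurement plane and the storage change in the air column
below the sensor::

    NEE = F_CO2 + Sc        (µmol m-2 s-1, negative = uptake)

``F_CO2`` is the air density times the covariance of vertical-wind and
CO2 mixing-ratio fluctuations over one 30-min block.  ``Sc`` uses the
discrete single-height approach: the canopy air column is treated as
well mixed, so the storage flux is the change of column CO2 between
consecutive half hours divided by the averaging interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_GAS = 8.314  # J mol-1 K-1


@dataclass
class HighFrequencyBlock:
    """One 30-min block of high-frequency (typically 10 Hz) samples.

    ``w`` is vertical wind (m s-1) and ``c`` the CO2 mixing ratio
    (µmol mol-1 of dry air).  ``u`` and ``v`` are optional horizontal
    components, needed only for coordinate rotation.  ``rho_air`` is the
    molar air density (mol m-3).
    """

    w: np.ndarray
    c: np.ndarray
    rho_air: float
    sampling_rate: float = 10.0
    start_time: object = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.w.shape != self.c.shape or self.w.size < 2:
            raise ValueError("w and c must be equal-length arrays with >= 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.rho_air <= 0:
            raise ValueError("rho_air must be positive")


@dataclass
class StorageInputs:
    """Inputs of the discrete storage term.

    ``delta_c`` is the change in column-mean CO2 mixing ratio between
    consecutive half hours (µmol mol-1); ``z`` the measurement height (m);
    ``t_a`` air temperature (K); ``p_a`` ambient pressure (Pa);
    ``delta_t`` the averaging interval (s).
    """

    delta_c: float
    z: float = 11.0
    t_a: float = 300.0
    p_a: float = 101325.0
    delta_t: float = 1800.0
    r: float = R_GAS

    def __post_init__(self):
        if self.z <= 0 or self.t_a <= 0 or self.p_a <= 0 or self.delta_t <= 0:
            raise ValueError("z, t_a, p_a, delta_t must all be positive")


@dataclass
class NeeComponents:
    f_co2: float
    s_c: float
    nee: float


def double_rotation(block: HighFrequencyBlock) -> HighFrequencyBlock:
    """Rotate wind coordinates so mean lateral and vertical wind vanish.

    First rotation (yaw) aligns the x axis with the mean horizontal wind;
    second rotation (pitch) zeroes the mean vertical wind.  Scalar samples
    are untouched.  Per-sample wind-vector magnitude is conserved.
    """
    if block.u is None or block.v is None:
        raise ValueError("double rotation needs all three wind components")
    u, v, w = (np.asarray(a, dtype=float) for a in (block.u, block.v, block.w))
    ub, vb = u.mean(), v.mean()
    horiz = math.hypot(ub, vb)
    if horiz == 0.0:
        out = HighFrequencyBlock(w=w, c=block.c, rho_air=block.rho_air,
                                 sampling_rate=block.sampling_rate,
                                 start_time=block.start_time, u=u, v=v,
                                 flags=block.flags + ["rotation_undefined"])
        return out
    theta = math.atan2(vb, ub)
    u1 = u * math.cos(theta) + v * math.sin(theta)
    v1 = -u * math.sin(theta) + v * math.cos(theta)
    phi = math.atan2(w.mean(), u1.mean())
    u2 = u1 * math.cos(phi) + w * math.sin(phi)
    w2 = -u1 * math.sin(phi) + w * math.cos(phi)
    return HighFrequencyBlock(w=w2, c=block.c, rho_air=block.rho_air,
                              sampling_rate=block.sampling_rate,
                              start_time=block.start_time, u=u2, v=v1,
                              flags=list(block.flags))


def block_covariance_flux(block: HighFrequencyBlock) -> float:
    """Turbulent CO2 flux rho_air * mean(w'c') for one block (µmol m-2 s-1).

    Population (1/N) normalisation of the covariance, by convention.
    """
    w, c = block.w, block.c
    if np.ptp(w) == 0.0 or np.ptp(c) == 0.0:
        return 0.0  # zero fluctuation: exactly zero, no rounding residue
    return float(block.rho_air * np.mean((w - w.mean()) * (c - c.mean())))


def storage_term(s: StorageInputs) -> float:
    """Discrete storage flux Sc = dC * z / ((R*Ta/Pa) * dt) in µmol m-2 s-1."""
    molar_volume = s.r * s.t_a / s.p_a  # m3 mol-1
    return float(s.delta_c * s.z / (molar_volume * s.delta_t))


def assemble_nee(f_co2: float, s_c: float) -> NeeComponents:
    """NEE = F_CO2 + Sc; non-finite inputs propagate as missing (NaN)."""
    if not (np.isfinite(f_co2) and np.isfinite(s_c)):
        return NeeComponents(f_co2=f_co2, s_c=s_c, nee=float("nan"))
    return NeeComponents(f_co2=f_co2, s_c=s_c, nee=f_co2 + s_c)


def read_high_frequency(path) -> list[HighFrequencyBlock]:
    """Read a plain-text high-frequency file into 30-min blocks.

    Expected columns: ``timestamp,u,v,w,c`` plus a one-line header
    ``# rho_air=<mol m-3> sampling_rate=<Hz>``.  Rows are grouped into
    consecutive blocks of ``sampling_rate * 1800`` samples.
    """
    with open(path) as fh:
        meta = fh.readline()
        if not meta.startswith("#"):
            raise ValueError("missing metadata header line")
        kv = dict(tok.split("=") for tok in meta[1:].split())
        rho = float(kv["rho_air"])
        rate = float(kv["sampling_rate"])
        df = pd.read_csv(fh)
    n_per = int(rate * 1800)
    blocks = []
    for start in range(0, len(df) - n_per + 1, n_per):
        chunk = df.iloc[start:start + n_per]
        blocks.append(HighFrequencyBlock(
            w=chunk["w"].to_numpy(), c=chunk["c"].to_numpy(), rho_air=rho,
            sampling_rate=rate, start_time=chunk["timestamp"].iloc[0],
            u=chunk["u"].to_numpy(), v=chunk["v"].to_numpy()))
    return blocks
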