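"""Post-processing of wind-field quantities near cliffs.

A steady-state RANS solution of the airflow over an island provides, at
every grid point, the mean wind speed ``U`` (m s⁻¹) and the turbulent
kinetic energy ``k`` (J m⁻³).  Under the isotropy assumption
``u'² + v'² + w'² = 3u²`` the TKE collapses to a single "typical"
velocity perturbation

    u = sqrt((2/3) k / rho)

and the dimensionless turbulence intensity is ``I = u / U``.  Typical
values of ``I`` are ~0.1; values near 1 indicate highly variable winds
and occur mostly where the mean wind is weak (sheltered, leeward areas).

The module also carries the two pieces of plumbing that connect cliff
winds to reference measurements elsewhere: the logarithmic wind-profile
height adjustment (e.g. buoy records adjusted from 3.5 m to 2 m above
sea level) and the sea-to-cliff scaling constant, the mean over wind
directions of the ratio of cliff wind to the upwind at-sea wind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Air density used throughout, kg m^-3.  With rho = 1 the density drops
#: out of the velocity-perturbation formula.
DEFAULT_RHO = 1.0

#: Roughness length over land (the airflow model's value), m.
ROUGHNESS_LAND = 0.1

#: Roughness length over open sea, m.  Not fixed by the airflow model;
#: exposed as a configurable default.
ROUGHNESS_SEA = 0.001


def velocity_perturbation(k, rho: float = DEFAULT_RHO):
    """Typical velocity perturbation u (m s⁻¹) from TKE ``k`` (J m⁻³).

    u = sqrt((2/3) k / rho), assuming isotropic turbulence.

    Accepts scalars or arrays.  Raises ``ValueError`` for negative ``k``
    or non-positive ``rho``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("turbulent kinetic energy k must be >= 0")
    if rho <= 0:
        raise ValueError("air density rho must be > 0")
    u = np.sqrt((2.0 / 3.0) * k / rho)
    return float(u) if u.ndim == 0 else u


def turbulence_intensity(u, U):
    """Turbulence intensity I = u / U (dimensionless).

    Undefined where the mean wind vanishes: a zero ``U`` raises
    ``ValueError`` for scalars; for arrays the corresponding entries are
    returned as NaN (flagged, never silently infinite).
    """
    u_arr = np.asarray(u, dtype=float)
    U_arr = np.asarray(U, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("velocity perturbation u must be >= 0")
    scalar = u_arr.ndim == 0 and U_arr.ndim == 0
    if scalar:
        if U_arr <= 0:
            raise ValueError("turbulence intensity undefined for U <= 0")
        return float(u_arr / U_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        I = np.where(U_arr > 0, u_arr / np.where(U_arr > 0, U_arr, 1.0), np.nan)
    return I


@dataclass(frozen=True)
class WindSample:
    """A point sample of the wind field with derived quantities.

    Attributes
    ----------
    U : mean wind speed, m s⁻¹
    k : turbulent kinetic energy, J m⁻³
    rho : air density, kg m⁻³
    u : typical velocity perturbation sqrt((2/3)k/rho), m s⁻¹
    I : turbulence intensity u/U; NaN when U == 0
    """

    U: float
    k: float
    rho: float = DEFAULT_RHO
    u: float = field(init=False)
    I: float = field(init=False)

    def __post_init__(self):
        if self.U < 0:
            raise ValueError("mean wind speed U must be >= 0")
        u = velocity_perturbation(self.k, self.rho)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "I", u / self.U if self.U > 0 else math.nan)


@dataclass(frozen=True)
class WindProfile:
    """A logarithmic wind profile anchored at a reference height.

    U(z) = U_ref * ln(z / z0) / ln(z_ref / z0) for z > z0.
    """

    z_ref: float
    U_ref: float
    z0: float = ROUGHNESS_LAND

    def __post_init__(self):
        if not (self.z_ref > self.z0 > 0):
            raise ValueError("require z_ref > z0 > 0")
        if self.U_ref < 0:
            raise ValueError("U_ref must be >= 0")

    def wind_at(self, z: float) -> float:
        return adjust_wind_to_height(self.U_ref, self.z_ref, z, self.z0)


def adjust_wind_to_height(U1, z1: float, z2: float, z0: float):
    """Adjust a wind speed between heights on a logarithmic profile.

    U2 = U1 * ln(z2/z0) / ln(z1/z0).  Both heights must exceed the
    roughness length ``z0``.  Used e.g. to bring buoy records from
    3.5 m down to 2 m above sea level.
    """
    if z0 <= 0:
        raise ValueError("roughness length z0 must be > 0")
    if z1 <= z0 or z2 <= z0:
        raise ValueError("heights must lie strictly above the roughness length")
    U1 = np.asarray(U1, dtype=float)
    out = U1 * (math.log(z2 / z0) / math.log(z1 / z0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScalingConstant:
    """Cliff-to-sea wind ratio averaged over compass directions."""

    ratio: float
    direction_set: tuple = ()

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError("scaling ratio must be > 0")


def sea_to_cliff_ratio(
    paired_samples: Sequence[tuple],
    directions: Sequence[str] | None = None,
) -> ScalingConstant:
    """Scaling constant from per-direction (cliff U, sea U) pairs.

    The ratio is the mean over directions of cliff/sea (mean of ratios,
    matching per-direction normalisation by an upwind reference point),
    not the ratio of means.  A ratio < 1 means the cliffs are sheltered
    relative to open water in every direction on average.
    """
    pairs = list(paired_samples)
    if len(pairs) == 0:
        raise ValueError("at least one (cliff, sea) pair is required")
    cliff = np.array([p[0] for p in pairs], dtype=float)
    sea = np.array([p[1] for p in pairs], dtype=float)
    if np.any(sea <= 0):
        raise ValueError("all at-sea wind speeds must be > 0")
    if np.any(cliff < 0):
        raise ValueError("cliff wind speeds must be >= 0")
    ratio = float(np.mean(cliff / sea))
    dirs = tuple(directions) if directions is not None else ()
    return ScalingConstant(ratio=ratio, direction_set=dirs)


def derive_wind_table(grid: pd.DataFrame, rho: float = DEFAULT_RHO) -> pd.DataFrame:
    """Append derived u and I columns to a gridded (U, k) table.

    Expects columns ``U`` and ``k`` (extra columns such as x, y, z pass
    through untouched).  I is NaN where U == 0.
    """
    for col in ("U", "k"):
        if col not in grid.columns:
            raise ValueError(f"grid table is missing required column {col!r}")
    out = grid.copy()
    out["u"] = velocity_perturbation(out["k"].to_numpy(), rho)
    out["I"] = turbulence_intensity(out["u"].to_numpy(), out["U"].to_numpy())
    return out
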