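"""PAR attenuation with depth and experimental irradiance targets.

Downwelling PAR decays approximately exponentially with depth,
``E(z) = E(0)·exp(−K_PAR·z)``; the diffuse attenuation coefficient
K_PAR is the negative slope of ln(PAR) against depth (Kirk).  The
experimental irradiance for a benthic station is the daylight mean of
surface PAR propagated to station depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = ["IrradianceProfile", "AttenuationEstimate",
           "fit_kpar", "propagate", "daily_mean"]


@dataclass
class IrradianceProfile:
    """Vertical PAR profile: depths (m, increasing) and PAR values."""

    depths_m: Sequence[float]
    par: Sequence[float]
    date: str = ""

    def __post_init__(self):
        z = np.asarray(self.depths_m, dtype=float)
        p = np.asarray(self.par, dtype=float)
        if z.size != p.size:
            raise ValueError("depth and PAR series differ in length")
        if z.size < 3:
            raise ValueError("profile needs at least 3 points")
        if np.any(z < 0) or np.any(np.diff(z) <= 0):
            raise ValueError("depths must be non-negative and strictly increasing")
        if np.any(p <= 0):
            raise ValueError("PAR must be positive for log-linear fitting")
        self.depths_m = z
        self.par = p


@dataclass
class AttenuationEstimate:
    K_PAR: float  # m-1
    r2: float
    n: int
    negative_flag: bool = False


def fit_kpar(profile: IrradianceProfile) -> AttenuationEstimate:
    """K_PAR as −slope of the OLS regression of ln(PAR) on depth.

    A profile where PAR increases with depth yields a negative K and is
    flagged rather than rejected.
    """
    z = profile.depths_m
    lnp = np.log(profile.par)
    res = _sstats.linregress(z, lnp)
    k = -res.slope
    return AttenuationEstimate(K_PAR=float(k), r2=float(res.rvalue ** 2),
                               n=int(z.size), negative_flag=bool(k <= 0))


def propagate(E_surface: float, K_PAR: float, depth_m: float) -> float:
    """Beer–Lambert propagation: E(z) = E_surface·exp(−K_PAR·z)."""
    if E_surface < 0 or K_PAR < 0 or depth_m < 0:
        raise ValueError("E_surface, K_PAR and depth must be non-negative")
    return float(E_surface * np.exp(-K_PAR * depth_m))


def daily_mean(times_h, par) -> float:
    """Trapezoidal time-average of PAR over the daylight samples.

    Night samples (PAR ≤ 0) are excluded so the result is the mean
    irradiance over the photoperiod, the quantity an aquarium lamp is
    set to.  An all-dark series returns 0 with a warning.
    """
    t = np.asarray(times_h, dtype=float)
    p = np.asarray(par, dtype=float)
    if t.size == 0:
        raise ValueError("empty PAR series")
    day = p > 0
    if not np.any(day):
        warnings.warn("all-dark PAR series: daily mean is 0")
        return 0.0
    t, p = t[day], p[day]
    if t.size == 1:
        return float(p[0])
    return float(np.trapezoid(p, t) / (t[-1] - t[0]))
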