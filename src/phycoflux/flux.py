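"""Closed-chamber incubation fluxes: O2, inorganic and organic carbon.

One alga sits in a sealed, stirred chamber of known volume; dissolved
O2 is logged continuously and seawater is sampled at the start and end
for pH_T and total alkalinity.  From these, three area-normalised
rates follow:

* the O2 rate from the slope of the O2–time regression,
* net calcification from the alkalinity anomaly (2 eq of A_T are
  consumed per mole of CaCO3 precipitated),
* the organic carbon flux from the C_T drawdown after removing the
  calcification contribution (1 mol C_T per mole of CaCO3).

Sign conventions: Δ quantities are initial − final, so consumption is
positive.  Light rates are net production (positive = fixation/
release of O2); dark rates are reported as positive respiration
magnitudes.  Gross production is Pg = Pn + Rd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "ChamberIncubation",
    "MetabolicFluxes",
    "o2_rate",
    "calcification_rate",
    "carbon_rate",
    "gross_rate",
    "incubation_fluxes",
]

TREATMENTS = ("400T", "400T+3", "700T", "700T+3")
SEASONS = ("summer", "autumn", "winter", "spring")

#: Linear-regression quality below which the O2 slope is flagged.
DEFAULT_R2_THRESHOLD = 0.8


class InsufficientDataError(ValueError):
    pass


@dataclass
class ChamberIncubation:
    """One closed-chamber run with its bracketing water samples.

    O2 in μmol L⁻¹ against time in hours; A_T in μeq L⁻¹; volume in L,
    thallus surface in cm², duration in h.  ``irradiance`` is the PAR
    level at the chamber (0 for a dark run).
    """

    incubation_id: str
    treatment: str
    season: str
    irradiance: float
    duration_h: float
    volume_L: float
    surface_cm2: float
    o2_times_h: Sequence[float]
    o2_umol_L: Sequence[float]
    pH_T_initial: float = float("nan")
    pH_T_final: float = float("nan")
    A_T_initial: float = float("nan")
    A_T_final: float = float("nan")
    temperature: float = float("nan")
    salinity: float = 38.0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.volume_L <= 0 or self.surface_cm2 <= 0:
            raise ValueError("chamber volume and thallus surface must be positive")
        t = np.asarray(self.o2_times_h, dtype=float)
        o = np.asarray(self.o2_umol_L, dtype=float)
        if t.size != o.size:
            raise ValueError("O2 time and concentration series differ in length")
        if t.size >= 2 and t[-1] - t[0] > self.duration_h + 1e-9:
            raise ValueError("O2 series spans longer than the stated duration")
        self.o2_times_h = t
        self.o2_umol_L = o

    @property
    def is_dark(self) -> bool:
        return self.irradiance == 0


@dataclass
class MetabolicFluxes:
    """Area-normalised rates of one incubation (μmol cm⁻² h⁻¹).

    In the light ``Pn_*`` hold net production and ``G`` net
    calcification; in the dark ``Rd_*`` hold respiration (positive) and
    ``G_d`` dark calcification.  ``Pg_*`` are filled once a paired dark
    rate is supplied, by Pg = Pn + Rd.
    """

    incubation_id: str
    light: bool
    Pn_O2: Optional[float] = None
    Rd_O2: Optional[float] = None
    Pn_C: Optional[float] = None
    Rd_C: Optional[float] = None
    G: Optional[float] = None
    G_d: Optional[float] = None
    Pg_O2: Optional[float] = None
    Pg_C: Optional[float] = None
    o2_r2: Optional[float] = None
    o2_quality_flag: bool = False


def o2_rate(incubation: ChamberIncubation,
            r2_threshold: float = DEFAULT_R2_THRESHOLD):
    """O2 flux from the slope of the O2-versus-time regression.

    Returns ``(rate, r2, flagged)`` where rate = slope·V/S in
    μmol O2 cm⁻² h⁻¹, signed: positive in the light is net production,
    the dark slope is negative.  ``flagged`` marks r² below
    ``r2_threshold`` (the rate is still returned; quality control is
    the caller's decision).
    """
    t = np.asarray(incubation.o2_times_h, dtype=float)
    o2 = np.asarray(incubation.o2_umol_L, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(
            f"O2 regression needs >= 3 points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("O2 sample times must be strictly increasing")

    res = _sstats.linregress(t, o2)
    slope = res.slope  # μmol L-1 h-1
    r2 = float(res.rvalue ** 2) if not np.isnan(res.rvalue) else 0.0
    rate = slope * incubation.volume_L / incubation.surface_cm2
    return float(rate), r2, bool(r2 < r2_threshold)


def calcification_rate(A_T_initial: float, A_T_final: float,
                       duration_h: float, volume_L: float,
                       surface_cm2: float) -> float:
    """Net calcification by the alkalinity anomaly technique.

    G = ΔA_T·V / (2·Δt·S) with ΔA_T = initial − final in μeq L⁻¹;
    the factor 2 is the 2 eq of alkalinity consumed per mole of CaCO3.
    Negative G means net dissolution.
    """
    if duration_h <= 0 or volume_L <= 0 or surface_cm2 <= 0:
        raise ValueError("duration, volume and surface must all be positive")
    dAT = A_T_initial - A_T_final
    return dAT * volume_L / (2.0 * duration_h * surface_cm2)


def carbon_rate(C_T_initial: float, C_T_final: float, duration_h: float,
                volume_L: float, surface_cm2: float, G: float,
                light: bool) -> float:
    """Organic carbon flux from the C_T drawdown, corrected for CaCO3.

    ``C_T`` values are volumetric (μmol L⁻¹, speciation × density).
    The gross drawdown rate is D = ΔC_T·V/(Δt·S); subtracting the
    calcification rate G (1 mol C_T per mol CaCO3) leaves the organic
    flux.  In the light this is Pn (positive = fixation); in the dark
    the respiratory release is returned as positive Rd = −(D − G).
    """
    if G is None:
        raise ValueError(
            "calcification rate G is required to correct the C_T drawdown")
    if duration_h <= 0 or volume_L <= 0 or surface_cm2 <= 0:
        raise ValueError("duration, volume and surface must all be positive")
    drawdown = (C_T_initial - C_T_final) * volume_L / (duration_h * surface_cm2)
    organic = drawdown - G
    return organic if light else -organic


def gross_rate(Pn: float, Rd: float) -> float:
    """Gross production Pg = Pn + Rd (both in the same currency, Rd ≥ 0)."""
    if Rd < 0:
        raise ValueError("dark respiration must be a non-negative magnitude")
    return Pn + Rd


def incubation_fluxes(
    incubation: ChamberIncubation,
    density_kg_L: float = 1.028,
    constant_set: str = "roy1993",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> MetabolicFluxes:
    """All currencies for one incubation.

    Runs the O2 regression, the alkalinity anomaly, and — when the
    bracketing pH_T/A_T samples are present — the carbonate speciation
    needed for the carbon flux.  Per-kg C_T from the speciation is
    converted to μmol L⁻¹ with ``density_kg_L``, and the per-litre A_T
    samples are converted the opposite way for the solver.
    """
    from .carbonate import solve_from_pH_AT

    rate_o2, r2, flagged = o2_rate(incubation, r2_threshold)
    light = not incubation.is_dark

    have_chem = not (np.isnan(incubation.A_T_initial)
                     or np.isnan(incubation.A_T_final))
    fluxes = MetabolicFluxes(incubation_id=incubation.incubation_id,
                             light=light, o2_r2=r2, o2_quality_flag=flagged)
    if light:
        fluxes.Pn_O2 = rate_o2
    else:
        fluxes.Rd_O2 = -rate_o2  # consumption reported positive

    if not have_chem:
        return fluxes

    G = calcification_rate(incubation.A_T_initial, incubation.A_T_final,
                           incubation.duration_h, incubation.volume_L,
                           incubation.surface_cm2)
    if light:
        fluxes.G = G
    else:
        fluxes.G_d = G

    if not (np.isnan(incubation.pH_T_initial)
            or np.isnan(incubation.pH_T_final)):
        ct = []
        for pH, AT_L in ((incubation.pH_T_initial, incubation.A_T_initial),
                         (incubation.pH_T_final, incubation.A_T_final)):
            state = solve_from_pH_AT(pH, AT_L / density_kg_L,
                                     incubation.temperature,
                                     incubation.salinity, constant_set)
            ct.append(state.C_T * density_kg_L)  # μmol L-1
        organic = carbon_rate(ct[0], ct[1], incubation.duration_h,
                              incubation.volume_L, incubation.surface_cm2,
                              G, light)
        if light:
            fluxes.Pn_C = organic
        else:
            fluxes.Rd_C = organic
    return fluxes
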