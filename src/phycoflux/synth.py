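"""Seeded synthetic experiments with known ground truth.

The generator emulates a year-long 2 × 2 (pCO2 × temperature) aquarium
experiment on a Mediterranean crustose coralline alga: four seasonal
campaigns, 4–5 replicate algae per treatment, closed-chamber
incubations in the light and dark, and irradiance-response
measurement sets.  Every stage of the analysis pipeline can therefore
be exercised against the exact parameters that produced the data.

Ground truth per treatment × season is a Platt parameter set for
photosynthesis (Ps, α, β, Rd) and calcification (Gs, α_G, β_G, Gd)
whose magnitudes follow the seasonal pattern of the system being
emulated: summer rates two- to three-fold above winter, highest summer
rates under elevated pCO2 at ambient temperature, photoinhibition in
winter.  Chamber chemistry is generated forward: O2 drifts linearly at
the true metabolic rate, A_T drops by 2 eq per mole of CaCO3
precipitated, C_T by 1 mol per mole CaCO3 plus 1 mol per mole of C
fixed (photosynthetic quotient 1), and the final pH is solved from the
final (A_T, C_T) pair so the bracketing samples are chemically
self-consistent.

All randomness flows from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .carbonate import solve_from_pH_AT, DEFAULT_DENSITY_KG_L
from .flux import ChamberIncubation, TREATMENTS, SEASONS
from .light import LightResponseData, model_rate

__all__ = [
    "TreatmentDesign",
    "SyntheticTruth",
    "make_default_truth",
    "simulate_incubation",
    "simulate_pe_experiment",
    "generate_experiment",
    "ph_from_AT_CT",
]

#: Seasonal ambient temperature (°C) at 25 m in the emulated bay.
SEASON_TEMP = {"summer": 22.0, "autumn": 17.7, "winter": 13.3, "spring": 17.7}
#: Seasonal experimental irradiance (μmol photons m⁻² s⁻¹).
SEASON_IRRADIANCE = {"summer": 35.0, "autumn": 16.0, "winter": 6.0, "spring": 21.0}
#: Seasonal photoperiod, light:dark hours.
SEASON_PHOTOPERIOD = {"summer": (14, 10), "autumn": (10, 14),
                      "winter": (11, 13), "spring": (15, 9)}
#: Seasonal mean pH_T by pCO2 level (total scale) and A_T (μmol kg⁻¹).
SEASON_PH = {
    ("summer", "400"): 8.06, ("summer", "700"): 7.87,
    ("autumn", "400"): 8.09, ("autumn", "700"): 7.88,
    ("winter", "400"): 8.10, ("winter", "700"): 7.87,
    ("spring", "400"): 8.09, ("spring", "700"): 7.87,
}
SEASON_AT = {"summer": 2538.0, "autumn": 2526.0, "winter": 2540.0,
             "spring": 2483.0}


@dataclass(frozen=True)
class TreatmentDesign:
    """One treatment cell of the seasonal design."""

    treatment: str              # "400T", "400T+3", "700T", "700T+3"
    season: str
    pco2_target: float          # μatm
    temp_offset: float          # 0 or +3 °C
    ambient_temperature: float  # seasonal ambient, °C
    irradiance: float           # experimental PAR level
    photoperiod: tuple
    n_algae: int

    @property
    def temperature(self) -> float:
        return self.ambient_temperature + self.temp_offset

    def __post_init__(self):
        if self.n_algae < 2:
            raise ValueError("need at least 2 algae per treatment")
        if self.irradiance < 0:
            raise ValueError("irradiance must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of one treatment × season cell."""

    design: TreatmentDesign
    # photosynthesis–irradiance truth (O2 currency; PQ = 1 so C matches)
    Ps: float
    alpha: float
    beta: float
    Rd: float
    # calcification–irradiance truth
    Gs: float
    alpha_G: float
    beta_G: float
    Gd: float
    # noise model
    sigma_O2: float = 1.0       # μmol L⁻¹ on each O2 reading
    sigma_AT: float = 3.0       # μeq L⁻¹ on each A_T sample
    sigma_pH: float = 0.005     # on each pH reading
    rate_noise_frac: float = 0.05   # additive P–E rate noise, fraction of Ps
    jitter_cv: float = 0.10         # between-alga parameter CV
    # carbonate baseline
    pH_T: float = 8.06
    A_T: float = 2538.0         # μmol kg⁻¹
    temperature: float = 22.0
    salinity: float = 38.0

    def pn(self, E: float) -> float:
        return model_rate(E, self.Ps, self.alpha, self.beta, self.Rd,
                          "photosynthesis_O2")

    def g(self, E: float) -> float:
        return model_rate(E, self.Gs, self.alpha_G, self.beta_G, self.Gd,
                          "calcification")


# Seasonal base parameters (400 T cell): photosynthetic scale, initial
# slope, photoinhibition, dark respiration — magnitudes follow the
# system's seasonal pattern (summer 2–3× winter, photoinhibition in
# winter when grown at 6 μmol m⁻² s⁻¹).
_SEASON_BASE = {
    #          Ps     alpha   beta    Rd     Gs     aG     bG     Gd
    "summer": (1.25, 0.039, 0.002, 0.30, 0.45, 0.008, 0.001, 0.05),
    "autumn": (0.80, 0.045, 0.004, 0.15, 0.25, 0.006, 0.002, 0.03),
    "winter": (0.60, 0.050, 0.010, 0.09, 0.06, 0.005, 0.002, 0.01),
    "spring": (0.70, 0.045, 0.005, 0.15, 0.20, 0.006, 0.002, -0.005),
}

# Multiplicative treatment effects on (Ps, alpha, Gs): highest summer
# photosynthesis and calcification under elevated pCO2 at ambient T.
_TREATMENT_EFFECT = {
    "400T":   (1.00, 1.00, 1.00),
    "400T+3": (1.15, 0.95, 1.15),
    "700T":   (1.30, 0.87, 1.30),
    "700T+3": (1.03, 0.76, 0.95),
}


def make_design(season: str, treatment: str) -> TreatmentDesign:
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    pco2 = 700.0 if treatment.startswith("700") else 400.0
    offset = 3.0 if treatment.endswith("+3") else 0.0
    n = 4 if (treatment == "700T+3" and season in ("winter", "spring")) else 5
    return TreatmentDesign(
        treatment=treatment, season=season, pco2_target=pco2,
        temp_offset=offset, ambient_temperature=SEASON_TEMP[season],
        irradiance=SEASON_IRRADIANCE[season],
        photoperiod=SEASON_PHOTOPERIOD[season], n_algae=n)


def make_default_truth(season: str, treatment: str = "400T") -> SyntheticTruth:
    """Deterministic ground truth for one treatment × season cell."""
    design = make_design(season, treatment)
    Ps, a, b, Rd, Gs, aG, bG, Gd = _SEASON_BASE[season]
    fP, fa, fG = _TREATMENT_EFFECT[treatment]
    level = "700" if treatment.startswith("700") else "400"
    return SyntheticTruth(
        design=design,
        Ps=Ps * fP, alpha=a * fa, beta=b, Rd=Rd,
        Gs=Gs * fG, alpha_G=aG, beta_G=bG, Gd=Gd,
        pH_T=SEASON_PH[(season, level)], A_T=SEASON_AT[season],
        temperature=design.temperature, salinity=38.0)


def ph_from_AT_CT(A_T: float, C_T: float, temperature: float,
                  salinity: float = 38.0, constant_set: str = "roy1993",
                  lo: float = 6.5, hi: float = 9.0) -> float:
    """Invert the speciation: pH_T whose C_T at the given A_T matches.

    Bisection (Brent) on pH over [6.5, 9]; both arguments in per-kg
    units (μmol kg⁻¹).
    """
    def f(pH):
        return solve_from_pH_AT(pH, A_T, temperature, salinity,
                                constant_set).C_T - C_T
    return float(brentq(f, lo, hi, xtol=1e-12))


def simulate_incubation(truth: SyntheticTruth, E: float, duration_h: float,
                        volume_L: float, surface_cm2: float,
                        n_points: int = 10, seed: int = 0,
                        incubation_id: str = "",
                        density_kg_L: float = DEFAULT_DENSITY_KG_L,
                        ) -> ChamberIncubation:
    """One closed-chamber run generated forward from the truth.

    O2 drifts linearly at (Pn(E) or −Rd)·S/V with i.i.d. Gaussian
    noise; the final A_T sample reflects the true calcification, the
    final pH the true A_T/C_T pair.  At zero noise the flux pipeline
    recovers the true rates to numerical precision.
    """
    if n_points < 3:
        raise ValueError("O2 series needs at least 3 points")
    rng = np.random.default_rng(seed)
    rate_o2 = truth.pn(E) if E > 0 else -truth.Rd        # μmol O2 cm-2 h-1
    g_rate = truth.g(E) if E > 0 else truth.Gd           # μmol CaCO3 cm-2 h-1
    drift = rate_o2 * surface_cm2 / volume_L             # μmol L-1 h-1

    o2_0 = 230.0  # near-saturation seawater baseline, μmol L-1
    times = np.linspace(0.0, duration_h, n_points)
    o2_clean = o2_0 + drift * times
    if np.any(o2_clean < 0):
        raise ValueError("true rate would drive chamber O2 negative; "
                         "shorten the incubation")
    o2 = o2_clean + rng.normal(0.0, truth.sigma_O2, n_points)

    # chamber chemistry (per-litre units)
    AT0_L = truth.A_T * density_kg_L
    ct0_kg = solve_from_pH_AT(truth.pH_T, truth.A_T, truth.temperature,
                              truth.salinity).C_T
    CT0_L = ct0_kg * density_kg_L
    per_L = duration_h * surface_cm2 / volume_L
    organic_C = rate_o2 if E > 0 else -truth.Rd          # PQ = 1
    ATf_L = AT0_L - 2.0 * g_rate * per_L
    CTf_L = CT0_L - (g_rate + organic_C) * per_L
    pH_f = ph_from_AT_CT(ATf_L / density_kg_L, CTf_L / density_kg_L,
                         truth.temperature, truth.salinity)

    return ChamberIncubation(
        incubation_id=incubation_id or f"sim-{seed}",
        treatment=truth.design.treatment, season=truth.design.season,
        irradiance=E, duration_h=duration_h, volume_L=volume_L,
        surface_cm2=surface_cm2, o2_times_h=times, o2_umol_L=o2,
        pH_T_initial=truth.pH_T + rng.normal(0.0, truth.sigma_pH),
        pH_T_final=pH_f + rng.normal(0.0, truth.sigma_pH),
        A_T_initial=AT0_L + rng.normal(0.0, truth.sigma_AT),
        A_T_final=ATf_L + rng.normal(0.0, truth.sigma_AT),
        temperature=truth.temperature, salinity=truth.salinity)


DEFAULT_E_LEVELS = (0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 150.0, 300.0)


def simulate_pe_experiment(truth: SyntheticTruth, E_levels=DEFAULT_E_LEVELS,
                           n_replicates: int = 5, seed: int = 0,
                           mode: str = "photosynthesis_O2",
                           ) -> list[LightResponseData]:
    """Per-replicate irradiance-response measurement sets.

    Each replicate's parameters are jittered around the truth
    (lognormal, CV ``truth.jitter_cv``) and its rates carry additive
    Gaussian noise of ``truth.rate_noise_frac × Ps``.
    """
    E = np.asarray(E_levels, dtype=float)
    if np.unique(E).size < 5:
        raise ValueError("need at least 5 distinct irradiance levels")
    if 0.0 not in E:
        raise ValueError("E levels must include the dark point 0")
    rng = np.random.default_rng(seed)
    calc = mode == "calcification"
    scale, alpha, beta, off = ((truth.Gs, truth.alpha_G, truth.beta_G, truth.Gd)
                               if calc else
                               (truth.Ps, truth.alpha, truth.beta, truth.Rd))
    sigma = truth.rate_noise_frac * scale
    cv = truth.jitter_cv
    ln_sd = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    curves = []
    for r in range(n_replicates):
        jit = (rng.lognormal(-0.5 * ln_sd ** 2, ln_sd, size=4)
               if cv > 0 else np.ones(4))
        s_r, a_r, b_r, off_r = (scale * jit[0], alpha * jit[1],
                                beta * jit[2], off * jit[3])
        rate = model_rate(E, s_r, a_r, b_r, off_r, mode)
        rate = np.asarray(rate) + rng.normal(0.0, sigma, E.size)
        curves.append(LightResponseData(
            replicate_id=f"{truth.design.treatment}-{truth.design.season}-r{r+1}",
            mode=mode, irradiance=E, rate=rate,
            treatment=truth.design.treatment, season=truth.design.season))
    return curves


def generate_experiment(seed: int = 0, seasons=SEASONS, treatments=TREATMENTS,
                        duration_h: float = 2.0, volume_L: float = 0.2,
                        surface_cm2: float = 20.0, n_points: int = 10,
                        pe_seasons=("summer", "winter")):
    """Full synthetic campaign as tidy tables.

    Returns ``(incubations, o2_series, pe_rates, truths)`` where the
    first three are DataFrames in the pipeline CSV schemas and
    ``truths`` maps (season, treatment) to the generating
    :class:`SyntheticTruth`.  Light and dark chamber incubations are
    generated for every alga; irradiance-response sets only for the
    seasons with multi-level light campaigns.
    """
    ss = np.random.SeedSequence(seed)
    inc_rows, o2_rows, pe_rows = [], [], []
    truths = {}
    for season in seasons:
        for treatment in treatments:
            truth = make_default_truth(season, treatment)
            truths[(season, treatment)] = truth
            child = np.random.SeedSequence((seed, SEASONS.index(season),
                                            TREATMENTS.index(treatment)))
            subseeds = child.generate_state(2 * truth.design.n_algae + 1)
            for alga in range(truth.design.n_algae):
                for light, E in ((1, truth.design.irradiance), (0, 0.0)):
                    inc_id = f"{season}-{treatment}-a{alga+1}-{'L' if light else 'D'}"
                    inc = simulate_incubation(
                        truth, E, duration_h, volume_L, surface_cm2,
                        n_points=n_points,
                        seed=int(subseeds[2 * alga + (1 - light)]) % (2 ** 31),
                        incubation_id=inc_id)
                    inc_rows.append({
                        "incubation_id": inc_id, "treatment": treatment,
                        "season": season, "replicate": alga + 1,
                        "light": light, "irradiance": E,
                        "duration_h": duration_h, "volume_L": volume_L,
                        "surface_cm2": surface_cm2,
                        "ph_initial": inc.pH_T_initial,
                        "ph_final": inc.pH_T_final,
                        "at_initial_ueq_L": inc.A_T_initial,
                        "at_final_ueq_L": inc.A_T_final,
                        "temperature_C": inc.temperature,
                        "salinity": inc.salinity})
                    for t, o in zip(inc.o2_times_h, inc.o2_umol_L):
                        o2_rows.append({"incubation_id": inc_id,
                                        "time_h": t, "o2_umol_L": o})
            if season in pe_seasons:
                for mode in ("photosynthesis_O2", "calcification"):
                    curves = simulate_pe_experiment(
                        truth, n_replicates=truth.design.n_algae,
                        seed=int(subseeds[-1]) % (2 ** 31)
                        + (1 if mode == "calcification" else 0),
                        mode=mode)
                    for c in curves:
                        for E, r in zip(c.irradiance, c.rate):
                            pe_rows.append({
                                "replicate_id": c.replicate_id, "mode": mode,
                                "treatment": treatment, "season": season,
                                "irradiance": E, "rate": r})
    return (pd.DataFrame(inc_rows), pd.DataFrame(o2_rows),
            pd.DataFrame(pe_rows), truths)
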