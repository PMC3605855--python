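"""Seawater CO2-system speciation from the measured pair (pH_T, A_T).

The solver is closed-form: given pH on the total scale and total
alkalinity, the carbonate alkalinity follows by subtracting the borate
and water contributions, and the three inorganic carbon species are
partitioned with the carbonic acid dissociation constants.  Saturation
states for calcite and aragonite use the Mucci (1983) stoichiometric
solubility products and a calcium concentration proportional to
salinity.

Two sets of K1/K2 formulations are provided, both on the total pH
scale at surface pressure:

``roy1993``
    Roy et al. (1993) — the default, matching the behaviour of early
    CO2-system software for Mediterranean conditions.
``lueker2000``
    Lueker, Dickson & Keeling (2000), the contemporary community
    standard.

Phosphate and silicate alkalinity are not included (the minor bases
were not measured in the chamber protocol this package targets); for
oligotrophic Mediterranean seawater their contribution to A_T is below
a few μmol kg⁻¹.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

__all__ = [
    "EquilibriumConstants",
    "CarbonateState",
    "compute_constants",
    "solve_from_pH_AT",
    "mean_pH",
    "speciate_csv",
    "CONSTANT_SETS",
    "DEFAULT_CONSTANT_SET",
    "DEFAULT_SALINITY",
    "DEFAULT_DENSITY_KG_L",
]

CONSTANT_SETS = ("roy1993", "lueker2000")
DEFAULT_CONSTANT_SET = "roy1993"

#: Salinity is rarely logged alongside chamber samples; NW Mediterranean
#: surface water sits close to 38 on the practical scale.
DEFAULT_SALINITY = 38.0

#: Seawater density used to convert per-kg speciation to per-litre chamber
#: budgets (kg L⁻¹).
DEFAULT_DENSITY_KG_L = 1.028


class CarbonateDomainError(ValueError):
    """Input outside the validity range of the constant formulations."""


class InconsistentInputError(ValueError):
    """pH/A_T pair with no physical carbonate-species solution."""


@dataclass(frozen=True)
class EquilibriumConstants:
    """Thermodynamic constants of the CO2 system at one (T, S) state.

    All dissociation constants are on the total hydrogen-ion scale and
    in mol kg⁻¹ (Ksp in mol² kg⁻²); K0 is the CO2 solubility in
    mol kg⁻¹ atm⁻¹.  Evaluated at surface pressure.
    """

    K0: float
    K1: float
    K2: float
    KB: float
    Kw: float
    Ksp_cal: float
    Ksp_arag: float
    BT: float
    CaT: float
    temperature: float
    salinity: float
    constant_set: str = DEFAULT_CONSTANT_SET

    def provenance(self) -> dict:
        """Metadata block recording which formulations produced the set."""
        return {
            "constant_set": self.constant_set,
            "K1_K2": ("Roy et al. (1993)" if self.constant_set == "roy1993"
                      else "Lueker et al. (2000)"),
            "KB": "Dickson (1990)",
            "Kw": "Millero (1995)",
            "Ksp": "Mucci (1983)",
            "K0": "Weiss (1974)",
            "BT": "Uppstrom (1974)",
            "CaT": "0.01028*(S/35) mol/kg",
            "pH_scale": "total",
            "pressure": "surface",
            "temperature_C": self.temperature,
            "salinity": self.salinity,
        }


@dataclass(frozen=True)
class CarbonateState:
    """Full speciation of one seawater sample.

    Concentrations in μmol kg⁻¹ (A_T in μeq kg⁻¹), pCO2 in μatm,
    saturation states dimensionless.
    """

    pH_T: float
    A_T: float
    C_T: float
    pCO2: float
    CO2: float
    HCO3: float
    CO3: float
    Omega_c: float
    Omega_a: float
    temperature: float
    salinity: float
    constant_set: str = DEFAULT_CONSTANT_SET

    def as_dict(self) -> dict:
        return asdict(self)


def compute_constants(
    temperature: float,
    salinity: float,
    constant_set: str = DEFAULT_CONSTANT_SET,
) -> EquilibriumConstants:
    """Evaluate the CO2-system constants at (T, S), surface pressure.

    Parameters
    ----------
    temperature : float
        In-situ temperature, °C; must lie in [0, 40].
    salinity : float
        Practical salinity; must lie in [20, 42].
    constant_set : str
        ``"roy1993"`` (default) or ``"lueker2000"`` for K1/K2.

    Returns
    -------
    EquilibriumConstants
    """
    if not 0.0 <= temperature <= 40.0:
        raise CarbonateDomainError(
            f"temperature {temperature} °C outside supported range [0, 40]")
    if not 20.0 <= salinity <= 42.0:
        raise CarbonateDomainError(
            f"salinity {salinity} outside supported range [20, 42]")
    if constant_set not in CONSTANT_SETS:
        raise ValueError(
            f"unknown constant set {constant_set!r}; choose from {CONSTANT_SETS}")

    T = temperature + 273.15
    S = salinity
    lnT = math.log(T)

    # Weiss (1974) CO2 solubility, mol kg-1 atm-1
    lnK0 = (-60.2409 + 93.4517 * (100.0 / T) + 23.3585 * math.log(T / 100.0)
            + S * (0.023517 - 0.023656 * (T / 100.0)
                   + 0.0047036 * (T / 100.0) ** 2))
    K0 = math.exp(lnK0)

    if constant_set == "lueker2000":
        pK1 = (3633.86 / T - 61.2172 + 9.6777 * lnT
               - 0.011555 * S + 0.0001152 * S * S)
        pK2 = (471.78 / T + 25.929 - 3.16967 * lnT
               - 0.01781 * S + 0.0001122 * S * S)
        K1, K2 = 10.0 ** -pK1, 10.0 ** -pK2
    else:  # roy1993
        sqS = math.sqrt(S)
        lnK1 = (2.83655 - 2307.1266 / T - 1.5529413 * lnT
                + (-0.20760841 - 4.0484 / T) * sqS + 0.08468345 * S
                - 0.00654208 * S ** 1.5 + math.log(1.0 - 0.001005 * S))
        lnK2 = (-9.226508 - 3351.6106 / T - 0.2005743 * lnT
                + (-0.106901773 - 23.9722 / T) * sqS + 0.1130822 * S
                - 0.00846934 * S ** 1.5 + math.log(1.0 - 0.001005 * S))
        K1, K2 = math.exp(lnK1), math.exp(lnK2)

    # Dickson (1990) boric acid, total scale
    sqS = math.sqrt(S)
    lnKB = ((-8966.90 - 2890.53 * sqS - 77.942 * S
             + 1.728 * S ** 1.5 - 0.0996 * S * S) / T
            + 148.0248 + 137.1942 * sqS + 1.62142 * S
            + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
            + 0.053105 * sqS * T)
    KB = math.exp(lnKB)

    # Millero (1995) water dissociation
    lnKw = (148.9802 - 13847.26 / T - 23.6521 * lnT
            + (-5.977 + 118.67 / T + 1.0495 * lnT) * sqS - 0.01615 * S)
    Kw = math.exp(lnKw)

    # Mucci (1983) stoichiometric solubility products
    log10T = math.log10(T)
    log10_Kc = (-171.9065 - 0.077993 * T + 2839.319 / T + 71.595 * log10T
                + (-0.77712 + 0.0028426 * T + 178.34 / T) * sqS
                - 0.07711 * S + 0.0041249 * S ** 1.5)
    log10_Ka = (-171.945 - 0.077993 * T + 2903.293 / T + 71.595 * log10T
                + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
                - 0.10018 * S + 0.0059415 * S ** 1.5)

    BT = 0.0004157 * S / 35.0          # Uppstrom (1974)
    CaT = 0.01028 * S / 35.0           # conservative with salinity

    return EquilibriumConstants(
        K0=K0, K1=K1, K2=K2, KB=KB, Kw=Kw,
        Ksp_cal=10.0 ** log10_Kc, Ksp_arag=10.0 ** log10_Ka,
        BT=BT, CaT=CaT,
        temperature=temperature, salinity=salinity,
        constant_set=constant_set,
    )


def _fugacity_coefficient(temperature: float) -> float:
    # Weiss (1974) virial expression for the CO2 fugacity coefficient at 1 atm
    T = temperature + 273.15
    B = -1636.75 + 12.0408 * T - 3.27957e-2 * T * T + 3.16528e-5 * T ** 3
    delta = 57.7 - 0.118 * T
    R = 83.14472  # cm3 bar mol-1 K-1
    P = 1.01325   # bar
    return math.exp((B + 2.0 * delta) * P / (R * T))


def solve_from_pH_AT(
    pH_T: float,
    A_T: float,
    temperature: float,
    salinity: float = DEFAULT_SALINITY,
    constant_set: str = DEFAULT_CONSTANT_SET,
) -> CarbonateState:
    """Speciate the CO2 system from pH (total scale) and total alkalinity.

    Parameters
    ----------
    pH_T : float
        pH on the total hydrogen-ion scale, in [6.5, 9].
    A_T : float
        Total alkalinity, μmol kg⁻¹ (μeq kg⁻¹).
    temperature, salinity : float
        In-situ state; salinity defaults to 38 (NW Mediterranean).
    constant_set : str
        K1/K2 formulation, see :func:`compute_constants`.

    Returns
    -------
    CarbonateState
        With C_T, pCO2 (fugacity-corrected, μatm), the three carbon
        species and the calcite/aragonite saturation states.

    Notes
    -----
    The carbonate alkalinity is obtained as
    ``A_C = A_T − A_B − [OH⁻] + [H⁺]`` and split between bicarbonate
    and carbonate with K2: ``A_C = [HCO3⁻](1 + 2 K2/[H⁺])``.
    """
    if not 6.5 <= pH_T <= 9.0:
        raise CarbonateDomainError(f"pH_T {pH_T} outside supported range [6.5, 9]")
    if A_T <= 0:
        raise CarbonateDomainError(f"A_T must be positive, got {A_T}")

    k = compute_constants(temperature, salinity, constant_set)
    AT = A_T * 1e-6  # mol kg-1
    H = 10.0 ** (-pH_T)

    borate_alk = k.BT * k.KB / (k.KB + H)
    OH = k.Kw / H
    carb_alk = AT - borate_alk - OH + H
    if carb_alk <= 0:
        raise InconsistentInputError(
            f"carbonate alkalinity non-positive ({carb_alk:.3e} mol/kg) for "
            f"pH_T={pH_T}, A_T={A_T}")

    HCO3 = carb_alk / (1.0 + 2.0 * k.K2 / H)
    CO3 = HCO3 * k.K2 / H
    CO2 = HCO3 * H / k.K1
    CT = CO2 + HCO3 + CO3
    fCO2 = CO2 / k.K0                       # atm
    pCO2 = fCO2 / _fugacity_coefficient(temperature)

    return CarbonateState(
        pH_T=pH_T, A_T=A_T,
        C_T=CT * 1e6, pCO2=pCO2 * 1e6,
        CO2=CO2 * 1e6, HCO3=HCO3 * 1e6, CO3=CO3 * 1e6,
        Omega_c=k.CaT * CO3 / k.Ksp_cal,
        Omega_a=k.CaT * CO3 / k.Ksp_arag,
        temperature=temperature, salinity=salinity,
        constant_set=constant_set,
    )


def mean_pH(pH_values) -> float:
    """Average pH by averaging hydrogen-ion activity.

    pH is a log quantity; the physically meaningful mean converts each
    value to [H⁺], averages, and converts back:
    ``−log10(mean(10^−pH_i))``.  The result never exceeds the
    arithmetic mean of the pH values.
    """
    vals = np.asarray(list(pH_values), dtype=float)
    if vals.size == 0:
        raise ValueError("mean_pH requires at least one pH value")
    return float(-np.log10(np.mean(10.0 ** (-vals))))


# ---------------------------------------------------------------------------
# CSV interface

_INPUT_COLUMNS = ["sample_id", "pH_total", "alkalinity_umol_kg",
                  "temperature_C", "salinity"]


def speciate_csv(
    in_path,
    out_path=None,
    constant_set: str = DEFAULT_CONSTANT_SET,
    default_salinity: float = DEFAULT_SALINITY,
) -> pd.DataFrame:
    """Speciate every row of a sample CSV, optionally writing the result.

    The input needs columns ``sample_id, pH_total, alkalinity_umol_kg,
    temperature_C`` and optionally ``salinity`` (filled with
    ``default_salinity`` when absent).  The output appends ``ct,
    pco2_uatm, co2, hco3, co3, omega_calcite, omega_aragonite``.  When
    ``out_path`` is given, a JSON provenance sidecar naming the
    constant set is written next to it.
    """
    df = pd.read_csv(in_path)
    missing = [c for c in _INPUT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    if "salinity" not in df.columns:
        df["salinity"] = default_salinity
    df["salinity"] = df["salinity"].fillna(default_salinity)

    states = [
        solve_from_pH_AT(r.pH_total, r.alkalinity_umol_kg, r.temperature_C,
                         r.salinity, constant_set)
        for r in df.itertuples()
    ]
    out = df.copy()
    out["ct"] = [s.C_T for s in states]
    out["pco2_uatm"] = [s.pCO2 for s in states]
    out["co2"] = [s.CO2 for s in states]
    out["hco3"] = [s.HCO3 for s in states]
    out["co3"] = [s.CO3 for s in states]
    out["omega_calcite"] = [s.Omega_c for s in states]
    out["omega_aragonite"] = [s.Omega_a for s in states]

    if out_path is not None:
        out.to_csv(out_path, index=False)
        prov = compute_constants(
            float(df["temperature_C"].iloc[0]),
            float(df["salinity"].iloc[0]), constant_set).provenance()
        with open(str(out_path) + ".provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2)
    return out
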