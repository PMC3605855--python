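"""Configuration-driven orchestration of the full analysis chain.

``run_pipeline`` reads the chamber-incubation and irradiance-response
CSVs, computes carbonate chemistry, metabolic fluxes, curve fits and
the per-season factorial statistics, and writes tidy result tables
plus a JSON provenance report.  A single malformed incubation is
excluded with a logged reason rather than aborting the run.

CSV schemas (UTF-8, header row):

incubations.csv
    incubation_id, treatment, season, replicate, light, irradiance,
    duration_h, volume_L, surface_cm2, ph_initial, ph_final,
    at_initial_ueq_L, at_final_ueq_L, temperature_C, salinity
o2_series.csv
    incubation_id, time_h, o2_umol_L
pe_rates.csv
    replicate_id, mode, treatment, season, irradiance, rate
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import (DEFAULT_CONSTANT_SET, DEFAULT_DENSITY_KG_L,
                        DEFAULT_SALINITY, mean_pH, solve_from_pH_AT)
from .flux import ChamberIncubation, gross_rate, incubation_fluxes
from .light import PlattModel
from .stats import FactorialAnova, bonferroni_alpha

logger = logging.getLogger("phycoflux")

__all__ = ["RunConfig", "run_pipeline"]

_INCUBATION_COLUMNS = [
    "incubation_id", "treatment", "season", "replicate", "light",
    "irradiance", "duration_h", "volume_L", "surface_cm2",
    "ph_initial", "ph_final", "at_initial_ueq_L", "at_final_ueq_L",
    "temperature_C", "salinity",
]

#: Flux responses fed to the per-season factorial ANOVAs, in the order
#: they are analysed (the Bonferroni divisor defaults to their count).
FLUX_RESPONSES = ("Rd_O2", "Rd_C", "G_d", "Pn_O2", "Pn_C",
                  "Pg_O2", "Pg_C", "G")


@dataclass
class RunConfig:
    incubations_csv: str = ""
    o2_series_csv: str = ""
    pe_rates_csv: str = ""
    out_dir: str = "results"
    salinity: float = DEFAULT_SALINITY
    density_kg_L: float = DEFAULT_DENSITY_KG_L
    constant_set: str = DEFAULT_CONSTANT_SET
    pin_dark_offset: bool = False
    bonferroni_divisor: int | None = None   # default: responses per season
    base_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _load_incubations(cfg: RunConfig):
    inc = pd.read_csv(cfg.incubations_csv)
    missing = [c for c in _INCUBATION_COLUMNS if c not in inc.columns]
    if missing:
        raise ValueError(
            f"incubations CSV missing required columns: {missing}")
    o2 = pd.read_csv(cfg.o2_series_csv)
    series = {k: g.sort_values("time_h") for k, g in o2.groupby("incubation_id")}
    out, excluded = [], []
    for row in inc.itertuples():
        try:
            s = series.get(row.incubation_id)
            if s is None:
                raise ValueError("no O2 series for incubation")
            chamber = ChamberIncubation(
                incubation_id=row.incubation_id, treatment=row.treatment,
                season=row.season, irradiance=float(row.irradiance),
                duration_h=float(row.duration_h),
                volume_L=float(row.volume_L),
                surface_cm2=float(row.surface_cm2),
                o2_times_h=s["time_h"].to_numpy(),
                o2_umol_L=s["o2_umol_L"].to_numpy(),
                pH_T_initial=float(row.ph_initial),
                pH_T_final=float(row.ph_final),
                A_T_initial=float(row.at_initial_ueq_L),
                A_T_final=float(row.at_final_ueq_L),
                temperature=float(row.temperature_C),
                salinity=float(row.salinity))
            out.append((row, chamber))
        except (ValueError, TypeError) as exc:
            logger.warning("excluding incubation %s: %s", row.incubation_id, exc)
            excluded.append({"incubation_id": row.incubation_id,
                             "reason": str(exc)})
    return out, excluded


def _flux_table(records, cfg: RunConfig):
    rows, excluded = [], []
    for meta, chamber in records:
        try:
            fl = incubation_fluxes(chamber, density_kg_L=cfg.density_kg_L,
                                   constant_set=cfg.constant_set)
        except (ValueError, RuntimeError) as exc:
            logger.warning("excluding incubation %s: %s",
                           chamber.incubation_id, exc)
            excluded.append({"incubation_id": chamber.incubation_id,
                             "reason": str(exc)})
            continue
        rows.append({
            "incubation_id": chamber.incubation_id,
            "treatment": chamber.treatment, "season": chamber.season,
            "replicate": meta.replicate, "light": int(fl.light),
            "irradiance": chamber.irradiance,
            "Pn_O2": fl.Pn_O2, "Rd_O2": fl.Rd_O2,
            "Pn_C": fl.Pn_C, "Rd_C": fl.Rd_C,
            "G": fl.G, "G_d": fl.G_d,
            "o2_r2": fl.o2_r2, "o2_quality_flag": int(fl.o2_quality_flag)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df, excluded
    # pair light and dark per alga to fill gross production
    for (season, treat, rep), grp in df.groupby(
            ["season", "treatment", "replicate"]):
        light = grp[grp["light"] == 1]
        dark = grp[grp["light"] == 0]
        if len(light) == 1 and len(dark) == 1:
            li, di = light.index[0], dark.index[0]
            for cur in ("O2", "C"):
                pn, rd = df.at[li, f"Pn_{cur}"], df.at[di, f"Rd_{cur}"]
                if pd.notna(pn) and pd.notna(rd):
                    df.at[li, f"Pg_{cur}"] = gross_rate(pn, rd)
    return df, excluded


def _carbonate_summary(records, cfg: RunConfig):
    rows = []
    frame = pd.DataFrame([{
        "season": ch.season, "treatment": ch.treatment,
        "pH": ch.pH_T_initial, "AT_L": ch.A_T_initial,
        "T": ch.temperature, "S": ch.salinity}
        for _, ch in records])
    if frame.empty:
        return pd.DataFrame()
    for (season, treat), grp in frame.groupby(["season", "treatment"]):
        pH = mean_pH(grp["pH"])
        AT_kg = float(grp["AT_L"].mean()) / cfg.density_kg_L
        state = solve_from_pH_AT(pH, AT_kg, float(grp["T"].mean()),
                                 float(grp["S"].mean()), cfg.constant_set)
        rows.append({"season": season, "treatment": treat,
                     "pH_T": pH, "A_T_umol_kg": AT_kg,
                     "pCO2_uatm": state.pCO2, "CT_umol_kg": state.C_T,
                     "CO2": state.CO2, "HCO3": state.HCO3, "CO3": state.CO3,
                     "omega_calcite": state.Omega_c,
                     "omega_aragonite": state.Omega_a})
    return pd.DataFrame(rows)


def _pe_tables(cfg: RunConfig):
    if not cfg.pe_rates_csv:
        return pd.DataFrame(), pd.DataFrame()
    pe = pd.read_csv(cfg.pe_rates_csv)
    params, summaries = [], []
    for (mode, season, treat), grp in pe.groupby(
            ["mode", "season", "treatment"]):
        try:
            res = PlattModel.from_dataframe(grp, mode=mode).fit()
        except (ValueError, RuntimeError) as exc:
            logger.warning("curve fitting failed for %s/%s/%s: %s",
                           mode, season, treat, exc)
            continue
        params.append(res.params_frame())
        for s in res.by_treatment():
            row = {"mode": mode, "season": s.season, "treatment": s.treatment,
                   "n": s.n}
            for k, v in s.mean.items():
                row[f"{k}_mean"] = v
            for k, v in s.se.items():
                row[f"{k}_se"] = v
            summaries.append(row)
    params_df = (pd.concat(params, ignore_index=True)
                 if params else pd.DataFrame())
    return params_df, pd.DataFrame(summaries)


def _stats_tables(flux: pd.DataFrame, cfg: RunConfig):
    anova_rows, letter_rows = [], []
    if flux.empty:
        return pd.DataFrame(), pd.DataFrame()
    for season, sgrp in flux.groupby("season"):
        per_alga = sgrp.groupby(["treatment", "replicate"]).agg(
            {r: "mean" for r in FLUX_RESPONSES if r in sgrp}).reset_index()
        responses = [r for r in FLUX_RESPONSES
                     if r in per_alga and per_alga[r].notna().sum() >= 8]
        divisor = cfg.bonferroni_divisor or max(len(responses), 1)
        alpha_adj = bonferroni_alpha(cfg.base_alpha, divisor)
        for resp in responses:
            sub = per_alga[per_alga[resp].notna()]
            pco2 = sub["treatment"].str[:3].to_numpy()
            temp = np.where(sub["treatment"].str.endswith("+3"), "T+3", "T")
            try:
                model = FactorialAnova.from_dataframe(
                    sub.assign(pco2=pco2, temp=temp), resp, season=season,
                    alpha=cfg.base_alpha, n_analyses=divisor)
                res = model.fit()
            except (ValueError, RuntimeError) as exc:
                logger.warning("ANOVA skipped for %s/%s: %s",
                               season, resp, exc)
                continue
            for eff in ("pco2", "temp", "interaction"):
                e = res.anova.effects.loc[eff]
                anova_rows.append({
                    "season": season, "response": resp, "effect": eff,
                    "df1": int(e.df1), "df2": int(e.df2),
                    "F": e.F, "p": e.p,
                    "significant": int(e.p < alpha_adj),
                    "log_transformed": int(res.anova.log_transformed),
                    "alpha_adjusted": alpha_adj})
            for cell, letter in res.posthoc.letters.items():
                letter_rows.append({"season": season, "response": resp,
                                    "cell": cell, "letters": letter})
    return pd.DataFrame(anova_rows), pd.DataFrame(letter_rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the result bundle to ``cfg.out_dir``.

    Returns a dict of the output DataFrames keyed by table name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        records, excluded = _load_incubations(cfg)
        flux, flux_excl = _flux_table(records, cfg)
        excluded += flux_excl
        carb = _carbonate_summary(records, cfg)
        pe_params, pe_summary = _pe_tables(cfg)
        anova, letters = _stats_tables(flux, cfg)

        tables = {"fluxes": flux, "carbonate_summary": carb,
                  "pe_params": pe_params, "pe_treatment_summary": pe_summary,
                  "anova": anova, "posthoc_letters": letters}
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        provenance = {
            "software": f"phycoflux {__version__}",
            "constant_set": cfg.constant_set,
            "salinity_default": cfg.salinity,
            "density_kg_L": cfg.density_kg_L,
            "base_alpha": cfg.base_alpha,
            "bonferroni_divisor": cfg.bonferroni_divisor,
            "seed": cfg.seed,
            "n_incubations": len(records),
            "excluded": excluded,
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
        tables["provenance"] = provenance
        return tables
    finally:
        logger.removeHandler(handler)
        handler.close()
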