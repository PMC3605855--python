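"""Irradiance-response (P–E and G–E) curve fitting.

The model is the exponential saturation curve of Platt et al. (1980)
with a photoinhibition term, plus an additive dark offset:

    photosynthesis:  Pn(E) = Ps·(1 − e^(−αE/Ps))·e^(−βE/Ps) − Rd
    calcification:   G(E)  = Gs·(1 − e^(−αE/Gs))·e^(−βE/Gs) + Gd

Ps (Gs) is the maximum rate in the absence of photoinhibition, α the
initial slope, β the photoinhibition coefficient, and Rd (Gd) the dark
rate.  Derived photophysiological parameters:

    Pg_max = Ps·[α/(α+β)]·[β/(α+β)]^(β/α)   (gross maximum)
    Pn_max = Pg_max − Rd                      (G_max = Gg_max + Gd)
    E_k    = Pg_max / α                       (saturating irradiance)
    E_c    : smallest E > 0 with Pn(E) = 0    (compensation irradiance)

Fitting is per replicate (one alga, one curve) with deterministic
multi-start bounded least squares; treatment-level values are the mean
± SE over replicate fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, brentq

__all__ = [
    "LightResponseData",
    "PlattFit",
    "DerivedParams",
    "TreatmentCurveSummary",
    "PlattModel",
    "PlattResults",
    "model_rate",
    "fit_platt",
    "derive_params",
    "summarize_treatment",
]

MODES = ("photosynthesis_O2", "photosynthesis_C", "calcification")

PARAM_NAMES = ("scale", "alpha", "beta", "offset")


class FitError(RuntimeError):
    """Raised when no start of the bounded least squares converges."""


@dataclass
class LightResponseData:
    """Rates of one replicate measured at several irradiance levels.

    ``irradiance`` in μmol photons m⁻² s⁻¹ (must include the dark
    point E = 0), ``rate`` in μmol cm⁻² h⁻¹.
    """

    replicate_id: str
    mode: str
    irradiance: Sequence[float]
    rate: Sequence[float]
    treatment: str = ""
    season: str = ""

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        E = np.asarray(self.irradiance, dtype=float)
        r = np.asarray(self.rate, dtype=float)
        if E.size != r.size:
            raise ValueError("irradiance and rate differ in length")
        if np.any(E < 0):
            raise ValueError("irradiance must be non-negative")
        if np.unique(E).size < 5:
            raise ValueError("need at least 5 distinct irradiance levels")
        if 0.0 not in E:
            raise ValueError("the dark point E = 0 is required")
        self.irradiance = E
        self.rate = r


@dataclass
class PlattFit:
    """Fitted parameters of one replicate curve."""

    scale: float
    alpha: float
    beta: float
    offset: float
    mode: str
    rss: float
    converged: bool
    n_obs: int = 0
    replicate_id: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.scale, self.alpha, self.beta, self.offset])


@dataclass
class DerivedParams:
    """Photophysiological parameters derived from a fit.

    ``Ec`` is ``None`` (with ``ec_reason``) when the net curve never
    crosses zero — dark respiration exceeding the gross maximum — or,
    for calcification with Gd ≥ 0, when compensation is undefined.
    """

    Pg_max: float
    Pn_max: float
    Ek: float
    Ec: Optional[float]
    ec_reason: str = ""
    replicate_id: str = ""


@dataclass
class TreatmentCurveSummary:
    treatment: str
    season: str
    n: int
    mean: dict
    se: dict


def model_rate(E, scale: float, alpha: float, beta: float, offset: float,
               mode: str = "photosynthesis_O2"):
    """Evaluate the Platt curve with dark offset at irradiance E.

    For the photosynthesis modes the offset Rd is subtracted (dark
    value −Rd); for calcification the dark rate Gd is added (dark value
    Gd, which may be negative = dissolution).
    """
    E = np.asarray(E, dtype=float)
    gross = scale * (1.0 - np.exp(-alpha * E / scale)) * np.exp(-beta * E / scale)
    if mode == "calcification":
        out = gross + offset
    else:
        out = gross - offset
    return out if out.ndim else float(out)


def _gross(E, scale, alpha, beta):
    return scale * (1.0 - np.exp(-alpha * E / scale)) * np.exp(-beta * E / scale)


def fit_platt(data: LightResponseData) -> PlattFit:
    """Bounded least-squares fit of the Platt-with-offset curve.

    Deterministic: initial α from the OLS slope through the lowest
    three nonzero-E points, scale from the observed maximum, and a
    fixed two-point multi-start on β ∈ {0, α/100}.  Bounds keep
    scale > 0, α > 0, β ≥ 0 and, for photosynthesis, offset ≥ 0.
    """
    E, y = data.irradiance, data.rate
    if np.ptp(y) == 0:
        raise FitError("degenerate data: all rates identical")
    calc = data.mode == "calcification"
    sign = 1.0 if calc else -1.0  # offset enters with this sign

    dark = float(np.mean(y[E == 0]))
    offset0 = dark if calc else max(-dark, 1e-6)
    # initial slope from the 3 lowest nonzero irradiances
    nz = np.argsort(E)[np.sort(E) > 0][:3]
    Elo, ylo = E[nz], y[nz] - dark
    denom = float(np.dot(Elo, Elo))
    alpha0 = max(float(np.dot(Elo, ylo) / denom), 1e-6) if denom > 0 else 1e-3
    scale0 = max(float(np.max(y)) - sign * offset0, 1e-6)

    def resid(p):
        s, a, b, off = p
        return _gross(E, s, a, b) + sign * off - y

    lo = [1e-12, 1e-12, 0.0, 0.0 if not calc else -np.inf]
    hi = [np.inf, np.inf, np.inf, np.inf]
    best = None
    for beta0 in (0.0, alpha0 / 100.0):
        x0 = np.clip([scale0, alpha0, beta0, offset0],
                     [1e-9, 1e-9, 0.0, lo[3] if np.isfinite(lo[3]) else -1e6],
                     None)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("Platt fit failed to converge from all starts")

    s, a, b, off = best.x
    return PlattFit(scale=float(s), alpha=float(a), beta=float(b),
                    offset=float(off), mode=data.mode,
                    rss=float(2.0 * best.cost), converged=True,
                    n_obs=int(E.size), replicate_id=data.replicate_id)


def _pg_max(scale: float, alpha: float, beta: float) -> float:
    # [β/(α+β)]^(β/α) evaluated in log space; limit 1 as β → 0
    if beta < 1e-12 * alpha:
        return scale
    r = beta / alpha
    return scale * (alpha / (alpha + beta)) * math.exp(
        r * math.log(beta / (alpha + beta)))


def derive_params(fit: PlattFit, E_max: float = 2000.0) -> DerivedParams:
    """Closed-form Pg_max, Pn_max (or G_max), E_k; E_c by root search.

    E_c is the first positive root of the net curve, bracketed between
    0 and the irradiance of the gross maximum.  For photosynthesis it
    exists iff 0 < Rd < Pg_max; for calcification with Gd ≥ 0 the curve
    never crosses zero and E_c is reported missing.
    """
    pg = _pg_max(fit.scale, fit.alpha, fit.beta)
    calc = fit.mode == "calcification"
    net_max = pg + fit.offset if calc else pg - fit.offset
    ek = pg / fit.alpha

    ec, reason = None, ""
    dark_value = fit.offset if calc else -fit.offset
    if dark_value >= 0:
        reason = "dark rate non-negative: curve never crosses zero"
    elif net_max <= 0:
        reason = ("dark offset exceeds the gross maximum: "
                  "no compensation irradiance")
    else:
        # irradiance of the gross maximum (infinite when β = 0)
        if fit.beta > 1e-12 * fit.alpha:
            # stationary point of the gross curve
            e_peak = (fit.scale / fit.alpha) * math.log(
                (fit.alpha + fit.beta) / fit.beta)
        else:
            e_peak = E_max
        f = lambda E: model_rate(E, fit.scale, fit.alpha, fit.beta,
                                 fit.offset, fit.mode)
        hi = e_peak
        if f(hi) <= 0:  # numerical edge: expand/shrink bracket
            reason = "net curve non-positive over the search bracket"
        else:
            ec = float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14))

    return DerivedParams(Pg_max=pg, Pn_max=net_max, Ek=ek, Ec=ec,
                         ec_reason=reason, replicate_id=fit.replicate_id)


def summarize_treatment(fits, derived, treatment: str,
                        season: str) -> TreatmentCurveSummary:
    """Mean ± SE of fitted and derived parameters over replicates.

    Fit per alga, then aggregate; SE = sd/√n (ddof=1).  E_c enters the
    summary only for replicates where it exists.
    """
    rows = []
    for f, d in zip(fits, derived):
        rows.append({"scale": f.scale, "alpha": f.alpha, "beta": f.beta,
                     "offset": f.offset, "Pg_max": d.Pg_max,
                     "Pn_max": d.Pn_max, "Ek": d.Ek, "Ec": d.Ec})
    df = pd.DataFrame(rows)
    n = len(df)
    mean = df.mean().to_dict()
    if n >= 2:
        se = (df.std(ddof=1) / math.sqrt(n)).to_dict()
    else:
        se = {k: float("nan") for k in df.columns}
    return TreatmentCurveSummary(treatment=treatment, season=season,
                                 n=n, mean=mean, se=se)


# ---------------------------------------------------------------------------
# Model/Results facade

class PlattModel:
    """Irradiance-response model over one or many replicate curves.

    Parameters
    ----------
    data : LightResponseData or sequence of LightResponseData
        One curve per alga.

    Examples
    --------
    >>> model = PlattModel(curves)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data):
        if isinstance(data, LightResponseData):
            data = [data]
        self.data = list(data)
        if not self.data:
            raise ValueError("PlattModel needs at least one replicate curve")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str) -> "PlattModel":
        """Build from a tidy frame with columns replicate_id, treatment,
        season, irradiance, rate (one row per measurement)."""
        curves = []
        for rid, grp in df.groupby("replicate_id", sort=True):
            curves.append(LightResponseData(
                replicate_id=str(rid), mode=mode,
                irradiance=grp["irradiance"].to_numpy(),
                rate=grp["rate"].to_numpy(),
                treatment=str(grp["treatment"].iloc[0]) if "treatment" in grp else "",
                season=str(grp["season"].iloc[0]) if "season" in grp else ""))
        return cls(curves)

    def fit(self) -> "PlattResults":
        fits = [fit_platt(d) for d in self.data]
        derived = [derive_params(f) for f in fits]
        return PlattResults(self, fits, derived)


class PlattResults:
    """Per-replicate fits plus treatment-level aggregation."""

    def __init__(self, model: PlattModel, fits, derived):
        self.model = model
        self.fits = fits
        self.derived = derived

    def params_frame(self) -> pd.DataFrame:
        """One row per replicate: fitted and derived parameters."""
        rows = []
        for d0, f, d in zip(self.model.data, self.fits, self.derived):
            rows.append({
                "replicate_id": f.replicate_id, "treatment": d0.treatment,
                "season": d0.season, "mode": f.mode,
                "scale": f.scale, "alpha": f.alpha, "beta": f.beta,
                "offset": f.offset, "Pg_max": d.Pg_max, "Pn_max": d.Pn_max,
                "Ek": d.Ek,
                "Ec": float("nan") if d.Ec is None else d.Ec,
                "rss": f.rss,
            })
        return pd.DataFrame(rows)

    def by_treatment(self) -> list:
        out = []
        df = self.params_frame()
        for (tr, se), grp in df.groupby(["treatment", "season"], sort=True):
            idx = grp.index
            out.append(summarize_treatment(
                [self.fits[i] for i in idx], [self.derived[i] for i in idx],
                tr, se))
        return out

    def summary(self) -> str:
        df = self.params_frame()
        lines = ["Platt irradiance-response fits",
                 "=" * 62,
                 f"replicates: {len(df)}   mode: {self.fits[0].mode}", ""]
        agg = df.groupby(["treatment", "season"], sort=True).agg(
            n=("scale", "size"), Pg_max=("Pg_max", "mean"),
            alpha=("alpha", "mean"), Ek=("Ek", "mean"))
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(agg.to_string())
        return "\n".join(lines)
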