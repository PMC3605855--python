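"""Per-season 2 (pCO2) × 2 (temperature) factorial analysis.

The design crosses two pCO2 levels (ambient ≈ 400 μatm, elevated ≈
700 μatm) with two temperatures (ambient T, T + 3 °C), with 4–5
replicate algae per cell and a fresh set of algae each season.  The
analysis chain per response:

1. assumption checks — Shapiro–Wilk normality on residuals, Levene
   homogeneity across cells — with an optional log transform when
   either fails;
2. two-way ANOVA with Type III sums of squares and sum-to-zero
   contrasts (robust to the unequal cell sizes);
3. Tukey–Kramer studentized-range comparisons among the four
   treatment cells (the unequal-n form of Tukey's HSD, the
   Spjotvoll–Stoline flavour), summarised as compact letters;
4. a Bonferroni-adjusted α shared across the family of responses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _sstats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "FactorialDataset",
    "AnovaTable",
    "PosthocResult",
    "AssumptionReport",
    "FactorialAnova",
    "FactorialResults",
    "check_assumptions",
    "two_way_anova",
    "tukey_posthoc",
    "bonferroni_alpha",
    "compact_letters",
]

PCO2_LEVELS = ("400", "700")
TEMP_LEVELS = ("T", "T+3")


class DegenerateDataError(ValueError):
    pass


@dataclass
class FactorialDataset:
    """Observations of one response under the 2×2 design.

    ``values``, ``pco2`` (∈ {"400","700"}), ``temp`` (∈ {"T","T+3"})
    are parallel sequences, one entry per alga.
    """

    response: str
    values: np.ndarray
    pco2: np.ndarray
    temp: np.ndarray
    season: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=str)
        self.temp = np.asarray(self.temp, dtype=str)
        if not (len(self.values) == len(self.pco2) == len(self.temp)):
            raise ValueError("values, pco2 and temp must be the same length")
        if set(np.unique(self.pco2)) != set(PCO2_LEVELS):
            raise ValueError(f"pCO2 factor must have levels {PCO2_LEVELS}")
        if set(np.unique(self.temp)) != set(TEMP_LEVELS):
            raise ValueError(f"temperature factor must have levels {TEMP_LEVELS}")
        for p, t in itertools.product(PCO2_LEVELS, TEMP_LEVELS):
            if not np.any((self.pco2 == p) & (self.temp == t)):
                raise ValueError(f"empty cell {p}/{t}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.values, "pco2": self.pco2,
                             "temp": self.temp,
                             "cell": [f"{p} {t}" for p, t in
                                      zip(self.pco2, self.temp)]})

    def cells(self) -> dict:
        df = self.to_frame()
        return {c: g["y"].to_numpy() for c, g in df.groupby("cell", sort=True)}


@dataclass
class AssumptionReport:
    shapiro_p: float
    levene_p: float
    log_transformed: bool
    data: FactorialDataset


@dataclass
class AnovaTable:
    """Type III two-way ANOVA of one response."""

    response: str
    effects: pd.DataFrame  # index: pco2, temp, interaction; cols F, df1, df2, p
    log_transformed: bool = False
    shapiro_p: float = float("nan")
    levene_p: float = float("nan")
    mse: float = float("nan")
    df_resid: int = 0

    def significant(self, effect: str, alpha: float) -> bool:
        return bool(self.effects.loc[effect, "p"] < alpha)


@dataclass
class PosthocResult:
    pairwise: pd.DataFrame  # columns group1, group2, meandiff, q, p
    letters: dict           # cell label -> letter string ("nd" when no pair differs)
    alpha: float


def bonferroni_alpha(base_alpha: float, n_analyses: int) -> float:
    """Family-wise threshold: α divided by the number of analyses."""
    if n_analyses < 1:
        raise ValueError("number of analyses must be >= 1")
    return base_alpha / n_analyses


def check_assumptions(data: FactorialDataset, alpha: float = 0.05,
                      allow_log: bool = True) -> AssumptionReport:
    """Shapiro–Wilk on cell-mean residuals and Levene across cells.

    If either test rejects at ``alpha`` and all values are positive,
    the returned report carries a log-transformed copy of the data with
    the transform flag set.
    """
    cells = data.cells()
    if any(len(v) < 3 for v in cells.values()):
        raise ValueError("assumption checks need >= 3 observations per cell")
    resid = np.concatenate([v - v.mean() for v in cells.values()])
    if np.ptp(data.values) == 0 or np.ptp(resid) == 0:
        raise DegenerateDataError("constant response: assumption tests undefined")
    sh_p = float(_sstats.shapiro(resid).pvalue)
    lev_p = float(_sstats.levene(*cells.values(), center="mean").pvalue)

    transformed = False
    out = data
    if allow_log and (sh_p < alpha or lev_p < alpha):
        if np.any(data.values <= 0):
            raise ValueError(
                "log transform requested for assumption failure but the "
                "response contains non-positive values")
        out = FactorialDataset(response=data.response + "_log",
                               values=np.log(data.values),
                               pco2=data.pco2, temp=data.temp,
                               season=data.season)
        transformed = True
    return AssumptionReport(shapiro_p=sh_p, levene_p=lev_p,
                            log_transformed=transformed, data=out)


def two_way_anova(data: FactorialDataset, ss_type: int = 3) -> AnovaTable:
    """Two-way fixed-effects ANOVA with Type III (default) or II SS.

    Sum-to-zero contrasts make the Type III tests well defined for the
    unequal cell sizes of the design (n = 4 vs 5).
    """
    df = data.to_frame()
    if all(np.ptp(v) == 0 for v in data.cells().values()):
        raise DegenerateDataError("response constant within cells: F undefined")
    model = smf.ols("y ~ C(pco2, Sum) * C(temp, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)

    name_map = {"C(pco2, Sum)": "pco2", "C(temp, Sum)": "temp",
                "C(pco2, Sum):C(temp, Sum)": "interaction"}
    resid_df = float(tab.loc["Residual", "df"])
    mse = float(tab.loc["Residual", "sum_sq"]) / resid_df
    rows = {}
    for key, label in name_map.items():
        rows[label] = {
            "F": float(tab.loc[key, "F"]),
            "df1": float(tab.loc[key, "df"]),
            "df2": resid_df,
            "p": float(tab.loc[key, "PR(>F)"]),
        }
    effects = pd.DataFrame(rows).T[["F", "df1", "df2", "p"]]
    return AnovaTable(response=data.response, effects=effects,
                      mse=mse, df_resid=int(resid_df))


def tukey_posthoc(data: FactorialDataset, anova: AnovaTable,
                  alpha: float = 0.05) -> PosthocResult:
    """Tukey–Kramer comparisons among the four treatment cells.

    The studentized-range statistic for cells i, j is
    ``q = |m_i − m_j| / sqrt(MSE/2·(1/n_i + 1/n_j))`` referred to the
    studentized-range distribution with k groups and the ANOVA residual
    df — the unequal-n generalisation of Tukey's HSD.  Letters are
    assigned with a greedy insert-absorb pass; "nd" when no pair
    differs at ``alpha``.
    """
    cells = data.cells()
    if any(len(v) < 2 for v in cells.values()):
        raise ValueError("post hoc comparisons need >= 2 observations per cell")
    labels = sorted(cells)
    k = len(labels)
    df_resid = anova.df_resid
    mse = anova.mse
    rows = []
    sig_pairs = set()
    for a, b in itertools.combinations(labels, 2):
        va, vb = cells[a], cells[b]
        diff = va.mean() - vb.mean()
        se = math.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(_sstats.studentized_range.sf(q, k, df_resid))
        rows.append({"group1": a, "group2": b, "meandiff": diff,
                     "q": q, "p": p})
        if p < alpha:
            sig_pairs.add((a, b))
    letters = compact_letters(labels, sig_pairs)
    return PosthocResult(pairwise=pd.DataFrame(rows), letters=letters,
                         alpha=alpha)


def compact_letters(groups, significant_pairs) -> dict:
    """Compact letter display via greedy insert-and-absorb.

    Groups sharing a letter are not significantly different.  Returns
    ``{group: "nd"}`` for every group when no pair is significant.
    """
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    if not sig:
        return {g: "nd" for g in groups}

    # each letter is the set of groups it covers; start with one letter
    letters = [set(groups)]
    for a, b in sorted(tuple(sorted(p)) for p in sig):
        for lset in list(letters):
            if a in lset and b in lset:
                letters.remove(lset)
                la, lb = lset - {b}, lset - {a}
                for cand in (la, lb):
                    if not any(cand <= other for other in letters):
                        letters.append(cand)
    # absorb letters fully contained in another
    letters = [l for l in letters
               if not any(l < other for other in letters)]
    letters.sort(key=lambda s: sorted(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, lset in enumerate(letters):
        for g in lset:
            out[g] += alphabet[i]
    return out


# ---------------------------------------------------------------------------
# Model/Results facade

class FactorialAnova:
    """2×2 factorial analysis of one response (statsmodels-style).

    ``fit()`` runs assumption checks (with optional log transform), the
    Type III two-way ANOVA and the Tukey–Kramer post hoc, and returns a
    :class:`FactorialResults`.
    """

    def __init__(self, data: FactorialDataset, alpha: float = 0.05,
                 n_analyses: int = 1, auto_transform: bool = True,
                 ss_type: int = 3):
        self.data = data
        self.base_alpha = alpha
        self.n_analyses = n_analyses
        self.auto_transform = auto_transform
        self.ss_type = ss_type

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       season: str = "", **kw) -> "FactorialAnova":
        """Build from a tidy frame with columns ``response`` (numeric),
        ``pco2`` and ``temp``."""
        ds = FactorialDataset(response=response,
                              values=df[response].to_numpy(),
                              pco2=df["pco2"].to_numpy(),
                              temp=df["temp"].to_numpy(), season=season)
        return cls(ds, **kw)

    def fit(self) -> "FactorialResults":
        report = check_assumptions(self.data, alpha=0.05,
                                   allow_log=self.auto_transform)
        anova = two_way_anova(report.data, ss_type=self.ss_type)
        anova.log_transformed = report.log_transformed
        anova.shapiro_p = report.shapiro_p
        anova.levene_p = report.levene_p
        alpha_adj = bonferroni_alpha(self.base_alpha, self.n_analyses)
        posthoc = tukey_posthoc(report.data, anova, alpha=alpha_adj)
        return FactorialResults(self, report, anova, posthoc, alpha_adj)


class FactorialResults:
    def __init__(self, model, assumptions, anova, posthoc, alpha_adjusted):
        self.model = model
        self.assumptions = assumptions
        self.anova = anova
        self.posthoc = posthoc
        self.alpha_adjusted = alpha_adjusted

    def summary(self) -> str:
        a = self.anova
        lines = [f"Two-way ANOVA: {self.model.data.response}"
                 + (f" [{self.model.data.season}]" if self.model.data.season else ""),
                 "=" * 60,
                 f"log-transformed: {a.log_transformed}   "
                 f"Shapiro p = {a.shapiro_p:.3f}   Levene p = {a.levene_p:.3f}",
                 ""]
        eff = a.effects.copy()
        eff["df"] = [f"({int(r.df1)},{int(r.df2)})" for r in eff.itertuples()]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(eff[["df", "F", "p"]].to_string())
        lines.append("")
        lines.append(f"Tukey–Kramer letters at Bonferroni-adjusted "
                     f"alpha = {self.alpha_adjusted:.4g}:")
        for g in sorted(self.posthoc.letters):
            lines.append(f"  {g:10s} {self.posthoc.letters[g]}")
        return "\n".join(lines)
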