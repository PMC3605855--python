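# Methods

## Carbonate-system speciation

Speciation starts from the measured pair (pH_T, A_T): with
[H⁺] = 10^(−pH_T), borate alkalinity A_B = B_T·K_B/(K_B + [H⁺]) and
[OH⁻] = K_w/[H⁺], the carbonate alkalinity is
A_C = A_T − A_B − [OH⁻] + [H⁺], split as
[HCO3⁻] = A_C/(1 + 2K₂/[H⁺]), [CO3²⁻] = [HCO3⁻]·K₂/[H⁺],
[CO2*] = [HCO3⁻]·[H⁺]/K₁. pCO2 is [CO2*]/K₀ divided by the Weiss
(1974) fugacity coefficient (~0.996–0.997); Ω = [Ca²⁺][CO3²⁻]/Ksp
with [Ca²⁺] = 0.01028·(S/35) mol kg⁻¹.

Assumptions and choices:

- **Constant set.** K1/K2 default to Roy et al. (1993); Lueker et
  al. (2000) is selectable (`constant_set="lueker2000"`). The Roy
  default was chosen because it reproduces the seasonal aquarium
  speciation table this pipeline targets to within ~1% in pCO2 and
  ~2% in Ω, i.e. it matches the behaviour of the CO2-system software
  generation used for such datasets; Lueker differs from those printed
  values by ~2% in pCO2 and ~5% in Ω. For new data the two sets agree
  to within a few percent and the choice is recorded in the provenance
  block of every output.
- **Salinity** defaults to 38.0 (NW Mediterranean surface water) and
  is configurable; chamber A_T in μeq L⁻¹ is converted to per-kg units
  with a fixed density of 1.028 kg L⁻¹ (configurable). Flux arithmetic
  itself stays volumetric.
- **Minor bases.** Phosphate and silicate alkalinity are omitted — the
  chamber protocol does not measure nutrients, and in oligotrophic
  Mediterranean water their A_T contribution is a few μmol kg⁻¹ at
  most. This biases A_C (hence C_T) high by the same small amount.
- **Scales and pressure.** Total hydrogen-ion scale only, surface
  pressure only. The Millero (1995) K_w formulation is nominally on
  the seawater scale; the scale difference enters only through the
  μmol-level [OH⁻] term of A_C and is far below the other
  uncertainties.
- Mean pH across replicate samples is computed by averaging [H⁺] and
  converting back, never by averaging pH directly.

## Chamber fluxes

Δ-quantities are **initial − final**, so consumption is positive. The
O2 rate uses every point of the series (no endpoint-only shortcut, no
outlier rejection); a regression r² below 0.8 (configurable) sets a
quality flag but does not drop the incubation — exclusion is an
explicit, logged decision of the pipeline caller. Dark respiration is
stored as a positive magnitude; gross production is reconstructed as
P_g = P_n + R_d, the only form consistent with the derived-parameter
identity P_n^max = P_g^max − R_d. The carbon flux requires the
calcification correction (1 mol C_T per mol CaCO3); it is an error,
not a default, to omit it.

## Irradiance-response fitting

The Platt curve with dark offset is fitted per replicate alga by
bounded trust-region least squares (`scipy.optimize.least_squares`,
bounds P_s, α > 0, β ≥ 0, R_d ≥ 0; the calcification offset G_d is
unconstrained because dark dissolution is physically real).
Initialisation is deterministic: α from the OLS slope through the
three lowest non-zero irradiances, P_s from the observed maximum plus
the dark offset guess, and a fixed two-point multi-start β ∈ {0,
α/100}; no randomness enters the fit, so refitting the same data is
bit-reproducible. The offset is a free parameter by default (the
fitted function includes the dark term); pinning it to the measured
dark rate is a pipeline option.

Numerical guards: [β/(α+β)]^(β/α) is evaluated in log space with
limit 1 when β < 10⁻¹²·α; E_c is bracketed on (0, E_peak] where
E_peak = (P_s/α)·ln((α+β)/β) is the stationary point of the gross
curve (E_peak → ∞ as β → 0, replaced by a wide fixed bracket), and
solved with Brent's method to 10⁻¹²; when R_d ≥ P_g^max (or G_d ≥ 0 in
calcification mode) E_c does not exist and is reported as missing with
a reason rather than as a number.

Treatment-level values are computed by fitting each alga separately
and then averaging (mean ± SE = sd/√n over replicates). This matches
how such experiments are reported, and it is deliberately *not* the
same as deriving parameters from averaged curves: the treatment E_k is
the mean of per-replicate P_g^max/α, not the ratio of the means.

## Factorial statistics

Each season is analysed independently (algae are replaced between
seasons, so there is no repeated measure). Per response: Shapiro–Wilk
on cell-centred residuals and Levene (centre = mean) across the four
cells at α = 0.05; on failure, a log transform is applied when the
response is strictly positive. The two-way ANOVA uses Type III sums of
squares with sum-to-zero contrasts, which is well defined for the
unbalanced cells (n = 4 vs 5); Type II is available by option. The
post hoc is Tukey–Kramer: q = |m_i − m_j| / √(MSE/2·(1/n_i + 1/n_j))
referred to the studentized-range distribution with k = 4 groups and
the ANOVA residual df — the unequal-n generalisation of Tukey's HSD
(the Spjotvoll–Stoline-style test; with equal n it reduces exactly to
classic HSD). Compact letters come from a greedy insert-absorb pass
and are guaranteed consistent with the pairwise decisions; "nd" marks
a response where no pair differs. The family-wise threshold is
α/(number of analyses); the divisor defaults to the number of
responses analysed per season and is a config input, since the family
definition is a scientific choice, not a computation.

## PAR field

K_PAR is −slope of the OLS regression of ln(PAR) on depth; a profile
in which PAR increases with depth yields a negative estimate and a
flag rather than an exception. The daily mean irradiance is a
trapezoidal time average over daylight samples only (PAR > 0), because
the quantity it feeds — the constant aquarium light level — applies
during the photoperiod.

## Synthetic-experiment generator

The generator emulates the seasonal aquarium design: four treatments
(400/700 μatm × T/T+3), seasonal ambient temperatures 22.0 / 17.7 /
13.3 / 17.7 °C, experimental irradiances 35 / 16 / 6 / 21 μmol photons
m⁻² s⁻¹, photoperiods 14:10 / 10:14 / 11:13 / 15:9, and n = 5 algae
per cell except n = 4 in the winter/spring elevated-pCO2 + warming
cell. Default ground-truth Platt parameters follow the seasonal
magnitudes of the emulated system (summer photosynthetic scale ~2×
winter; photoinhibition strongest in winter; highest summer
calcification under elevated pCO2 at ambient temperature), and the
carbonate baselines use the seasonal mean pH_T and A_T by pCO2 level.

Chamber series are generated forward from the truth: linear O2 drift
at (P_n(E) or −R_d)·S/V with i.i.d. Gaussian noise (σ = 1 μmol L⁻¹
default), A_T decremented by 2 eq per mole CaCO3, C_T by 1 mol per
mole CaCO3 plus 1 mol per mole of fixed carbon (photosynthetic
quotient fixed at 1), and the final pH solved by inverting the
speciation at the final (A_T, C_T) — so at zero noise every flux
estimator recovers the truth exactly, a property the tests rely on.
Measurement noise defaults: σ(A_T) = 3 μeq L⁻¹, σ(pH) = 0.005,
irradiance-response rate noise 5% of the scale parameter,
between-alga parameter variability lognormal with 10% CV. The default
irradiance ladder spans 0–300 μmol photons m⁻² s⁻¹ (eight levels
including darkness) so that both the initial slope and the
photoinhibition tail are identifiable.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: electrode drift and
autocorrelated O2 noise (noise is i.i.d.), nutrient alkalinity,
bubble or wall effects in chambers, diel physiology within an
incubation, necrosis-driven replacement of algae, and a
photosynthetic quotient different from 1 (real O2- and C-based rates
differ by the PQ; here they agree by construction).

## Problem sizes and determinism

Simulation-study tests use 50–300 seeded repetitions (fixed seed
lists, hypothesis derandomised), sizes at which every Monte-Carlo
check is stable to well under its assertion margin; a full synthetic
campaign (4 seasons × 4 treatments, light + dark chambers, two P–E
modes in summer and winter) runs the whole pipeline in a few seconds.
All randomness flows from explicit integer seeds; identical seeds give
byte-identical generated tables and pipeline outputs.

One calibration note: a ±2·SE band around a treatment mean of n = 5
replicates has exact Student-t coverage P(|t₄| ≤ 2) = 88.4%, not 95%;
checks of estimator calibration in the unit suite therefore test
against the t-based expectation rather than a nominal-normal one.

## Known limitations

- Only the (pH_T, A_T) input pair is supported — the pair the chamber
  protocol measures; no C_T–pCO2 or A_T–pCO2 solvers, no pressure
  correction, no pH-scale conversions.
- The alkalinity-anomaly method attributes all A_T change to CaCO3;
  nutrient uptake/release during an incubation would alias into G.
- Type III ANOVA with two levels per factor is insensitive to the
  contrast-coding subtleties that arise with ≥3 levels; extending the
  design would need care there.
- The Tukey–Kramer p-values are the standard conservative
  approximation for unequal n; exact Spjotvoll–Stoline critical points
  differ negligibly at these group sizes.
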