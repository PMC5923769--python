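# Methods

## Scope and model

`frackrisk` assesses residential exposure to a one-off spill of
hydraulic-fracturing flowback water into a 44,000,000 L surface reservoir,
under two scenarios:

* **drinking water** — daily ingestion of tap water (2.5 L/day), inhalation
  of volatiles released during household water use (15 m³/day), and dermal
  contact during a 43-minute daily bath/shower over the whole skin surface
  (20,900 cm²);
* **swimming** — a 1-hour daily swim with incidental ingestion
  (0.05 L/h), near-surface inhalation (the daily inhalation rate prorated
  over the event hour), and full-body immersion.

The spill mixes completely and instantaneously (no fate, transport,
attenuation or degradation), so the water concentration is
`C_w = C_fb * V_fb / V_pond`. Everything downstream is linear in `C_fb`
and `V_fb`, which the threshold inversions exploit.

## Exposure and risk equations

Chemical intakes follow the Superfund residential forms. With exposure
frequency EF (days/yr), duration ED (yr), body weight BW (kg) and averaging
time AT (days):

* ingestion: `CDI = C_w * IR_w * EF * ED / (BW * AT)`;
* inhalation (volatiles only): `C_air = K * C_w` with
  `K = 0.0005 * 1000 L/m3 = 0.5 L/m3`, then
  `CDI = C_air * IR_air * EF * ED / (BW * AT)`. The volatility gate is
  Henry's constant `> 1e-5 atm m3/mol` **and** molecular weight
  `< 200 g/mol`; in the packaged registry exactly benzene,
  1,2-dichloroethane and vinyl chloride pass it. Radionuclides bypass the
  gate (aerosolization during water use);
* dermal: per-event absorbed dose `DA_event = Kp * C_w * t_event`
  (mg/cm²-event), scaled by skin area, events/day and `EF*ED/(BW*AT)`.

Cancer risk is `dose * SF` per pathway, truncated at 1 (one-hit linear
form); the hazard quotient is `dose / RfD`. Route adjustments follow the
dermal-guidance conventions: `SF_dermal = SF_oral / ABS_GI`,
`RfD_dermal = RfD_oral * ABS_GI`, and the inhalation slope factor is
derived from the unit risk as `SF_inh = IUR * (BW / IR_air) * 1000`
(µg→mg). No inhalation reference concentrations are on record for the
registry's non-carcinogens, so the inhalation pathway contributes no hazard
quotient (its safe duration is reported as unbounded).

Radionuclide (radium-226/228) risk uses linear activity intake:
`risk = intake(pCi) * SF(risk/pCi)` for ingestion and inhalation, and an
immersion term `C_w * immersion_fraction * ED_years * SF_imm` for dermal
exposure. Radionuclide totals are never added to chemical cancer totals —
the slope-factor methodologies differ — and all outputs keep the partition:
`total_cancer_risk` (chemical carcinogens), `total_hazard_index`
(non-carcinogens), `total_radionuclide_risk`.

### Averaging-time conventions

Cancer metrics use a fixed lifetime averaging time (70 × 365 days).
Non-cancer metrics use a **fixed 30-year averaging window** rather than
`AT = ED × 365`: under the usual chronic convention the HQ is invariant in
ED and no finite "maximum safe duration" exists for it, so the inversion
adopts the fixed-window convention and flags it here. Both averaging times
are configuration fields, not constants.

## Default exposure factors

| factor | value | unit | basis |
|---|---|---|---|
| body weight | 70 | kg | adult default |
| water ingestion | 2.5 | L/day | residential tap water |
| air inhalation | 15 | m³/day | residential |
| exposure frequency | 350 (drinking), 365 (swim) | d/yr | residential default; daily swim |
| exposure duration (reference) | 30 | yr | residential default |
| AT (cancer / noncancer) | 25,550 / 10,950 | d | lifetime / fixed window |
| bath event | 43 | min/day | exposure-factors central value |
| skin surface | 20,900 | cm² | total body |
| swim ingestion | 0.05 | L/h | incidental |
| volatilization factor | 0.5 | L/m³ | household-use model |
| immersion fraction | 43/1440 (drinking), 1/24 (swim) | – | event schedule |

## The contaminant registry

22 analytes: 10 chemical carcinogens, 10 non-carcinogens, radium-226/228.
Each row carries toxicity factors (oral slope factor, inhalation unit risk,
oral reference dose), GI absorption fraction, dermal permeability,
Henry's constant, molecular weight, radionuclide slope factors, and a
concentration distribution (family + median + 95th-percentile anchors + the
source sample count). Values come from the standard EPA compilations
(IRIS/PPRTV/HEAST; dermal-guidance permeabilities, with the Potts–Guy
correlation where no recommended value exists; HEAST-style radionuclide
slope factors); the `notes` column records the source style per analyte.
The engine reads everything from the CSV — swapping the file swaps the
toxicology.

### Documented data-quality corrections to the published anchors

* **beryllium** — printed anchors out of order (median 0.02 > p95 0.01);
  swapped. The anchor constructor raises on such pairs unless the explicit
  swap override is used.
* **copper** — printed median 33,500 mg/L is inconsistent with its p95 of
  0.45 mg/L and with flowback chemistry; read as 0.335 (misplaced decimal).
* **nitrite** — p95 printed "060.81"; read as 60.81.
* **benzo(a)pyrene** — anchors print equal at two decimals (0.01/0.01),
  which would collapse the logistic to a point mass; p95 set to 0.015
  (median plus half the printing resolution).
* **radium-226 / radium-228** — printed medians (1.30 / 0.23 pCi/L against
  p95s of 48,190 / 4,470) imply log-sd ≈ 6.4/6.0, which would make radium
  concentration, not spill volume, the dominant sensitivity input and would
  contradict both the published sensitivity ordering and the median
  inhalation-risk statement. Read as 1,300 / 230 pCi/L (×1000 slip). The
  p95 anchors — which drive every threshold inversion — are used exactly as
  printed.
* **vinyl chloride, dibromochloromethane** — present in the published
  sensitivity table but absent from the distribution table; shipped with
  documented placeholders (vinyl chloride: a benzene-analog lognormal
  0.01/0.17, consistent with its reported upper-bound risk exceedance;
  dibromochloromethane: trace-THM lognormal 0.01/0.02).

## Distributions

Six families, each anchored so that `CDF(median) = 0.5` and
`CDF(p95) = 0.95` to 1e-9. Two-parameter families invert in closed form;
the triangular's lower bound is pinned at 0 (concentrations are
non-negative) and its mode/maximum follow from a bracketed root solve in
the relative mode, feasible only for p95/median between ~1.378 and ~2.651.
"Minimum extreme" is the Gumbel-minimum (left-skewed) distribution.
The Pareto scale is its minimum support point. Maximum-likelihood fitting
(location pinned at 0 for the non-negative families) supports the
synthetic-data recovery loop. Sampling is seeded; negative draws from the
unbounded families (logistic, Gumbel-min) are rejected and redrawn, since
concentrations are physical quantities, and spill volumes are rejected
above the 350,000 L observed maximum.

## Synthetic data

The study's raw inputs (national spill-report records; the 92-well
concentration dataset) are not deposited, so the package generates
structural stand-ins: 194 spill records with volumes from the fitted
lognormal (median 128 L, p95 114,900 L, truncated at 350,000 L), dates
uniform over 2008–2016 (no analytical weight), and per-analyte samples
sized by the published counts, with optional non-detect censoring
(non-detects reported at the detection limit, set to the 5th-percentile
concentration, and excluded from fitting; the vinyl chloride emulation
censors to a <5% detect rate). The generators reproduce marginal
distributions and censoring only — not spatial structure, inter-analyte
correlation, temporal trends, or reporting biases of real spill databases —
so passing tests demonstrate pipeline correctness, not fidelity to any
specific site.

## Monte Carlo and sensitivity

1000 trials by default (runs in well under a second; all published
stochastic comparisons use this size). Each trial draws one spill volume —
shared across analytes, since they co-occur in one spill — and one
concentration per analyte, independently (no correlation structure is
imposed). Summaries report min/Q1/median/Q3/p95/max with
linear-interpolation quantiles. Sensitivity is Spearman rank correlation
(mid-ranked ties) of each input against each total, with one-tailed
significance from the t-approximation; raw trials are used, not
aggregates. The prioritization comparison regresses log10 mean risk (and
log10 mean HI) on log10 mean concentration/MCL by ordinary least squares
across analytes (the quantities span several orders of magnitude; a linear-
scale fit would be dominated by a single point).

## Threshold inversions

"Maximum possible" inputs are operationalized as the 95th percentile of
every input distribution (configurable up to 1.0). Because risk is linear
in duration and in spill volume (risks are evaluated unclipped here),

```
D_max = D_ref * target / metric(D_ref),   V_max = V_ref * target / metric(V_ref)
```

with `D_ref = 30 yr` and `V_ref` the spill-volume percentile. A zero
metric (e.g. the inhalation hazard quotient) yields an "unbounded"
sentinel. The composite chemical spill threshold is the binding minimum of
the cancer (1e-6) and hazard-index (1.0) constraints; the radionuclide
threshold is computed separately, per the partition rule. The
dilution-equivalence helper reports `V_pond / V_spill` for transferring a
threshold to other water bodies.

## Known limitations

* Toxicity coefficients are compiled from current standard sources; the
  original assessment's appendix compilation is not public, and the
  inversion outputs scale directly with the dominant coefficients
  (benzo(a)pyrene and heptachlor-epoxide slope factors and permeabilities
  for the cancer total; barium and thallium RfDs for the HI). The
  drinking-water radionuclide duration reproduces the published 8 h within
  a few percent; the chemical-duration and spill-threshold figures
  reproduce to order of magnitude.
* The published radionuclide spill threshold (500 L) and the swimming
  toxicity threshold (15,000,000 L) are mutually inconsistent with the
  published duration tables under the linear model the assessment itself
  states (by factors of ~143 and ~25 respectively); this package's
  inversions are self-consistent (re-evaluating the metric at the returned
  threshold reproduces the target exactly) and agree with the
  duration-table side of each pair.
* The immersion ("body emersion") coefficients for radium are
  external-submersion-order estimates; published submersion dose
  coefficients make this pathway negligible next to inhalation, and no
  published coefficient reproduces a near-target median immersion risk.
* No fate/transport, attenuation, degradation, age-stratified receptors, or
  exposure-factor variability (only spill volume and concentrations are
  random); no goodness-of-fit model selection (the published family choices
  are taken as given); no censored-likelihood fitting.
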