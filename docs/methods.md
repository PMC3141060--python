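# Methods

This note documents the models, parameter choices and numerical conventions
behind `trialcea`. It covers the science the package implements; every
number quoted as a result here is computed by the test suite or the
acceptance script, not asserted.

## Study structure being modelled

A two-arm randomized comparison of hemodynamic monitoring in acute lung
injury: pulmonary artery catheter (PAC) versus central venous catheter
(CVC), roughly 300 subjects per arm, followed for one year with utility
interviews at 2, 6, 9 and 12 months and post-discharge resource-use
collection, then projected over remaining lifetime. The economic
evaluation takes a societal perspective in 2010 US dollars.

## Synthetic cohort generator

The patient-level data of such trials are not public, so the generator
emulates the published statistical structure. Its defaults *are* the study
conditions; they are not tuning knobs.

**Survival.** A two-piece exponential with constant hazards on (0, 60] and
(60, 365] days. Two published Kaplan-Meier anchors per arm identify the
model exactly:

    h1 = -ln S(60)/60,   h2 = [ln S(60) - ln S(365)]/305

Defaults: PAC S(60) = 0.738, S(365) = 0.644; CVC S(60) = 0.749,
S(365) = 0.681 (i.e. 2-month mortalities 26.2%/25.1% rising to one-year
mortalities 35.6%/31.9%). This is the minimal survival model uniquely
identified by two anchors; it cannot represent within-piece hazard trends.

**Hospital costs.** Log-normal, matched by method of moments to the
published arm mean ± SD ($96.8k ± 86.8k PAC, $89.2k ± 74.5k CVC). A
log-normal is the natural heavy-right-tail choice when the SD is of the
same order as the mean. Length of stay is likewise log-normal
(24.4 ± 19.2 vs 23.8 ± 19.8 days); a patient dying before the drawn
length of stay is recorded as a hospital death and accrues no
post-discharge activity.

**Utilities.** Interview waves are fixed at days 61, 183, 274 and 365
(2/6/9/12 months at 30.4375 days/month). Wave utilities are Beta draws
with mean set to the published wave medians — PAC 0.47 → 0.56 → 0.61 →
0.61, CVC 0.51 → 0.60 → 0.66 → 0.66 (improvement plateauing at 9 months)
— and dispersion 0.25, reflecting the wide inter-quartile ranges reported.
Interviews are only generated for patients alive at the wave and
discharged alive, retained with per-wave completion probability 0.72
(derived from 1385 completed interviews among 531 discharged-alive
subjects over four waves). 25% of interviews are flagged as proxy
responses; the flag is carried through I/O but does not enter any
computation.

**Resource use.** Each category is a prevalence Bernoulli gate times a
heavy-tailed positive part: negative-binomial (shifted to support ≥ 1) for
visit/item counts, rounded log-normal for day totals, both moment-matched
to the published per-user mean ± SD and prevalence per arm. The ICU share
of rehospitalization days is Binomial(total, 0.3) and the ventilated share
Binomial(ICU, 0.5) — these splits are not published; the values are
plausible ICU-utilization fractions chosen once. Lost work days
(prevalence 0.5, log-normal 90 ± 90 days) are likewise unpublished
placeholders. Medication counts convert to costed medication-days at 30
days per reported medication. Home-help and skilled-nursing categories are
carried in the schema (the cost-weight table prices them) but default to
zero prevalence.

**Covariates** (age, sex, race/ethnicity, APACHE III, fluid-strategy
assignment, tidal volume, delay to protocol, diagnosis) are drawn from
distributions matched to the published baseline table; they drive the
subgroup analyses and life-table lookups but not survival or costs, so the
generator plants no covariate effects beyond what the arms differ in.

All randomness flows through a single `numpy.random.Generator`; the
default seed is 20110721. Identical configurations produce byte-identical
cohorts.

**What passing tests do not show.** The generator draws costs, survival
and utilities independently within patient; real ALI data exhibit
correlation (sicker patients cost more, live shorter and report lower
utility). Calibration tests therefore validate marginal structure, not
joint structure, and absolute incremental estimates on synthetic cohorts
need not match the published point estimates.

## Costing

Post-discharge unit cost weights (2010 $): home oxygen $600 first day +
$6.50/day thereafter; home help $100/day; rehabilitation $800/day;
ventilated skilled-nursing $1500/day; ED visit $800; physician visit $200;
rehospitalization `total_days×1500 + ICU_days×(2600−1500) +
vent_days×(2800−2600)` — encoded as the increments 1100 and 200 exactly as
the formula composes them; medications $10/day; lost wages $200/day
(median US daily income). ED use is priced per visit by default (the
weight table is editable). Lost wages accrue only over reported lost work
days; no productivity loss is imputed after death. Hospital cost is
Σ department charge × cost-to-charge ratio, with an optional whole-hospital
fallback ratio; a missing ratio is a hard error naming the department. A
CPI table (CPI-U annual averages, shipped as an editable CSV) converts
other years' dollars to 2010.

## Outcomes

Kaplan-Meier estimation uses the product-limit estimator (ties: deaths
before censorings), cross-checked in tests against an exhaustive
hand-computed oracle on all 4-patient configurations.

Quality-adjusted survival is the trapezoid-rule area under the utility
curve on [0, min(death, 365)]: linear interpolation between interviews,
first observed value carried back to enrolment, last value carried forward
to the horizon, utility identically 0 from death. Carry-back is the
default hospital-phase convention; a `zero_until_discharge` mode holds
utility at zero until a supplied discharge day, for users who prefer the
more conservative convention. Patients discharged alive with no completed
interview receive their arm's median observed wave trajectory; the count
of imputed trajectories is logged and surfaced in the run manifest.

## Lifetime projection (reference case)

Survivors at one year accrue `multiplier × LE(age+1, sex, race)` further
years at utility 0.6/year and a configurable annual healthcare cost,
discounted at 3%/year for both costs and effects. Discounting uses the
end-of-year convention (the first projected year is discounted one full
period); the fractional final year accrues pro rata at the next period's
factor. The annuity is evaluated with `expm1/log1p` so that rate → 0
degenerates exactly to the undiscounted sum. Decedents within year one
keep their one-year accruals.

The annual cost beyond one year is **not** a published value; the shipped
default of $5,000/year is a placeholder of the right order for survey-based
annual health expenditure and should be set by the user. The bundled life
table is a **synthetic** Gompertz-Makeham construction (hazard
A + R·e^{αx}, with sex- and race-specific R) with the required
(age band, sex, race) schema and plausible US-like expectancies; drop in a
real life table as CSV (`age, sex, race, expectancy_years`) for
substantive use. Lookups clamp out-of-range ages to the nearest band (with
a warning) and map unknown race categories to `other`.

## Probabilistic sensitivity analysis

The default engine is a nonparametric patient-level bootstrap: each trial
resamples every arm with replacement to its original size and recomputes
the arm's mean lifetime cost — winsorized at the resample's own 95th
percentile — and mean lifetime QALYs. Winsorization applies to costs only
(heavy-tailed); effects are bounded and left untouched. The parametric
alternative draws each arm's (mean cost, mean QALY) from normal
distributions with supplied moments and an optional within-arm
correlation (default 0), and serves to reconstruct analyses from published
summary tables.

From the incremental cloud: quadrant probabilities are computed from
integer trial counts so the four masses sum to one exactly; a trial
exceeds willingness-to-pay λ when λ·ΔE − ΔC < 0, so dominated trials
exceed every threshold (an inferior strategy has no informative ICER, and
none is reported for a dominated point estimate); the CEAC is the
acceptable fraction over a λ grid (default $0–1000k/QALY in $10k steps),
with the λ→∞ plateau equal to the effect-positive fraction; the 95%
confidence ellipse comes from the cloud's mean and covariance scaled by
the χ²(2 df) quantile, so coverage converges to the nominal level on
normal clouds. Southwest-quadrant trials are ranked by net monetary
benefit, never by the sign-flipped raw ICER.

## Subgroups and sensitivity scenarios

Pre-specified strata: sex, age (<45, 45–64, >64), ethnicity, fluid
strategy, APACHE III (≤90 / >90), tidal volume (≤6.9 / >6.9 mL/kg), delay
to protocol (≤21.5 / >21.5 h), and diagnosis selections (sepsis,
pneumonia, aspiration — overlapping selections, not a partition). Ties go
to the lower stratum. Each subgroup re-runs the full PSA with the same
base seed, so the identity subgroup reproduces the all-cohort run exactly.

Built-in one-way scenarios: life-expectancy multiplier 0.5; post-year-1
utility ×0.75 and ×1.25; discount rate 5%; annual post-year-1 cost ×0.5
and ×2; physician cost ×0.5 and ×2 (implemented by scaling the
physician-visit weight, the closest implementable surrogate for
reimbursement changes). A direction worth noting: when the comparator arm
is longer-lived, *halving* the annual post-year-1 cost **widens** the
treatment-minus-comparator incremental cost and doubling narrows it,
because the projected tail accrues disproportionately to the longer-lived
arm; the tests assert exactly this direction.

## Problem sizes and determinism

Default runs use 300 patients/arm and 5000 PSA trials. Calibration tests
use 5000-patient arms (Kaplan-Meier anchor recovery within 3 Monte-Carlo
standard errors) and n = 10000 cost draws (moment recovery within 3%);
ellipse coverage is checked on a 50,000-point normal cloud within ±0.005.
End-to-end runs are reproducible: a manifest records the config hash and
seeds, and re-running a manifest's configuration reproduces every output
file byte for byte.

## Known limitations

- No within-patient correlation between costs, survival and utilities in
  the generator (see above).
- The one-piece-per-interval survival model cannot express late-hazard
  trends beyond what two anchors identify.
- GEE-style longitudinal inference on utilities, log-rank/Wilcoxon tests,
  value-of-information analysis and covariate-adjusted net-benefit
  regression are out of scope.
- The bundled life table and the post-year-1 annual cost are stand-ins;
  substantive conclusions require real values in the same schemas.
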