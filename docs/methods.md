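# Methods

This note documents the models implemented in `ssbtax`, their
assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic inputs

Analyses of beverage taxation normally run on restricted cohort and
household-survey microdata.  This package replaces those inputs with
parametric generators that emulate their statistical structure, so that
every downstream component can be tested end to end against known ground
truth.

**Population.**  Adults aged 30–90 with a flat-then-exponentially-
decaying age pyramid (knee at 60, scale 15 years) and a 50/50 sex split.
BMI is log-normal with an age gradient (mean 25.5/24.0 kg/m² for
men/women at 30, +0.05 kg/m² per year of age to a plateau at 65,
log-scale SD 0.15) and a secular trend of +0.002 log-units per calendar
year.  Beverage intake is a two-part mixture — Bernoulli consumer
indicator × Gamma positive part — which is what zero-inflated intake
distributions with non- and high-consumers require.  Defaults encode the
qualitative pattern that matters for tax-policy conclusions: men consume
more SSBs than women and younger adults more than older ones (consumer
probability 0.80/0.65 at age 30 for men/women, positive-part mean
420/260 ml/day, both decaying exponentially with age), while fruit-juice
intake is relatively higher among women.  Sugar densities default to
0.09 g/ml (SSB) and 0.10 g/ml (juice), and sugar intake is always
volume × density, exactly.  These magnitudes are plausibility-calibrated
placeholders, not survey fits; any real application must replace them
with estimates from dietary data.

**Household panels.**  Budget shares for {SSB, juice, other beverages}
are generated from the LA-AIDS share equation at log-normal prices and
expenditures, with the Stone price index resolved by fixed-point
iteration on the sample mean shares (the same deflation the estimator
uses, so the noiseless panel identifies the generating parameters
exactly).  Share noise is projected to sum to zero per household, so
adding-up is preserved exactly; a noise level that pushes shares outside
[0, 1] in more than 1% of households is rejected.

**Epidemiology.**  Incidence and case fatality for T2DM, CHD and stroke,
and other-cause mortality, are exponential-in-age (Gompertz-like) rate
schedules per sex, with a −1%/yr secular trend on other-cause mortality.
Prevalence is *derived*, not configured: a three-state illness–death
solver (well → diseased → dead, remission 0, annual forward integration,
rates → probabilities via 1 − exp(−rate)) produces the prevalence column,
so incidence, prevalence and mortality are mutually consistent by
construction.  For T2DM — whose excess mortality acts through a relative
risk on non-CVD mortality rather than a separate fatality channel — the
solver's excess-mortality input is built in two passes: first the
RR-implied non-CVD excess, then the additional CVD fatality that
diabetics incur through their higher CHD/stroke incidence.  The solver
reports start-of-age prevalence; simulated end-of-year states correspond
to the solver value one age later, and consistency checks align the two
conventions.

## Demand

The LA-AIDS system is estimated by dropping the last share equation,
imposing homogeneity (log price ratios against the dropped good) and
symmetry (shared γ coefficients across equations) as linear
reparameterisations, and solving the stacked two-equation system by OLS;
with identical regressors OLS coincides with SUR, and the cross-equation
symmetry constraint is handled in the parameter mapping.  The dropped
good's coefficients are recovered by adding-up, and the full coefficient
covariance is propagated through the same linear map, giving delta-method
standard errors for the elasticities (mean shares treated as fixed).
Uncompensated elasticities use the standard LA-AIDS formula
eᵢⱼ = −δᵢⱼ + γᵢⱼ/w̄ᵢ − βᵢw̄ⱼ/w̄ᵢ.

When estimation is skipped, the default German elasticity matrix is used:
own-price SSB −0.956 (SE 0.111), own-price juice −1.106 (SE 0.149),
SSB↔juice cross 0.052 (SE 0.097, applied symmetrically), pass-through
0.82 (SE 0.082); standard errors are derived from the published 95%
confidence intervals as (upper − lower)/3.92.  The residual "other
beverages" good gets unit own-price elasticity and zero cross response.
LA-AIDS with the Stone index was chosen over full nonlinear AIDS or
QUAIDS because it makes constrained estimation a linear problem and is
the standard treatment of household expenditure data; censored-demand
corrections and elasticity heterogeneity by age/sex are out of scope.

## Policy scenarios

Price effects apply once, at the policy start, and persist (a permanent
tax with an immediate demand response); consumption does not decay back.
Reformulation multiplies SSB sugar density by (1 − ρ·min(1, t/phase-in)),
i.e. a linear phase-in — "gradual" is otherwise unspecified and linear is
the minimal assumption.  The voluntary-reformulation comparator
linearises the observed 2%-per-6-years industry commitment and lets it
continue over the horizon.  In the extended ad valorem scenario both
goods are taxed and the cross-price term is disabled: with both prices
rising there is no cheaper in-category substitute; this is a documented
modelling choice, not an empirical claim.  Sensitivity settings (tax rate
0.10/0.30, reformulation 0.10, substitution off, elasticity overrides,
discount rates 0/0.05/0.10) are plain field overrides on the scenario
object.

## Risk pathways

Three pathways combine multiplicatively on the RR scale (the framework-
standard assumption when pathways are reported separately): BMI carries
RR per kg/m² for each disease (defaults 1.15 T2DM, 1.06 CHD, 1.04
stroke, references BMI 23); SSBs carry direct, BMI-independent RRs per
250 ml serving/day for T2DM (1.13) and CHD (1.17), toggleable for
structural-uncertainty analysis; prevalent T2DM multiplies CHD and
stroke incidence (RR 2.0) and non-CVD mortality (RR 1.7).  Sustained
sugar change shifts BMI linearly (β = 0.02 kg/m² per g/day) — a
deliberately conservative dose–response rather than an energy-balance
equation.  Exposure changes ramp linearly over a 5-year lag window per
disease.  All RR values are placeholder point estimates with log-normal
uncertainty in the range reported by meta-analyses; they are
configuration and must be confirmed against primary sources before any
substantive use.

Under reformulation the direct-effect exposure is *sugar-equivalent* SSB
volume, volume × (1 − ρ): direct cardiometabolic effects are attributed
to the sugar the beverage contains, so a 30% sugar reduction reduces the
direct effect accordingly even though volumes are unchanged.  For
price-only scenarios this coincides with using volume directly.

**Calibration.**  Individual probabilities rescale the stratum (sex ×
age) incidence by each person's RR relative to the stratum-mean RR
("individualised attributable fractions").  Two normalisation choices
make the stochastic and cohort engines agree in expectation:

1. in a counterfactual arm the denominator is the stratum-mean RR at
   *baseline* exposures (recomputed each year over current susceptibles),
   so mean incidence equals p₀(1 − PIF) — exactly what the life-table arm
   applies;
2. the prevalent-T2DM multiplier on CHD/stroke incidence and non-CVD
   mortality is normalised by 1 + (RR − 1)·prev(a, s) with the *expected*
   baseline T2DM prevalence from the epidemiology inputs, so baseline
   stratum means reproduce the input rates while the policy's effect on
   T2DM prevalence still propagates to CVD and mortality.

## Microsimulation

Discrete-time, annual, open cohort: entrants aged 30 are admitted each
year (as many as the initial population holds 30-year-olds), inherit the
entry year's exposure distribution including the secular BMI trend, and
are pre-generated so both arms see identical entrants.  Within a year the
order is: exposures → T2DM incidence → CHD → stroke → CHD fatality →
stroke fatality → other-cause mortality.  This lets incident T2DM raise
same-year cardiovascular risk; the order is fixed and mirrored exactly in
the life-table recursion.  CHD and stroke are absorbing first-ever-event
states; remission is zero everywhere.  Individuals age out after their
year at age 90.  BMI is fixed at its entry value apart from policy
shifts; cross-sectional age gradients come from the entry distribution
(a simplification relative to within-person weight trajectories, noted
as a limitation below).

Competing risks are resolved sequentially on independent pre-drawn
uniforms per (individual, year, event channel) rather than a single
multinomial, because per-cause channels preserve common random numbers
across arms: a baseline-vs-baseline comparison is *identically* zero, and
arm differences isolate the policy.  A consumed-channel guard turns any
double draw into a hard failure.  Mortality calibration factors
(target/raw per age/sex cell, bounded to [0.1, 10]) are available but
default to 1 because the synthetic mortality targets are the generator's
own rates.

Person-years count survivors of each year; incident cases count onsets
in the window regardless of same-year death.  "Cases prevented/
postponed" is the incident-count difference over the horizon — a case
delayed but still occurring within the horizon contributes case-years
(one per year of delay) but not cases; a case delayed beyond the horizon
counts as prevented.  Obesity outcomes are BMI ≥ 30 person-years
(case-years) and the peak yearly prevalence difference (cases), since
with fixed baseline BMI only the policy moves people across the
threshold.

## Life-table cohort model

The cross-validation engine is a proportional multistate life table over
closed 1-year cohorts (initial members by age/sex plus later 30-year-old
entrant cohorts, so both engines cover the same person-time).  Each
cohort carries the joint distribution over the eight T2DM × CHD × stroke
state combinations; the annual update applies the microsimulation's
event model cell by cell — scenario incidence = baseline incidence ×
(1 − PIF), the T2DM-dependent CHD/stroke multipliers, then mortality as
the product of per-channel survival probabilities.  Using the joint
distribution avoids the cross-disease independence approximation that
three separate disease tables would need at the mortality step.  PIFs
and stratum-mean excess-BMI series (for the utility weights) are
computed per disease, sex, age and year from the same synthetic
population the microsimulation runs on, without mortality selection.

The model is deterministic (bit-identical on identical inputs) and covers
BMI-mediated pathways only; scenarios with direct effects enabled are
rejected, matching the condition under which the two engines are
comparable.  Residual differences against the microsimulation are
second-order selection terms: PIFs are computed over whole strata rather
than current susceptibles, and within-person correlation between BMI and
disease state is not represented.  The agreement check therefore asks
that microsimulation means over replicate seeds fall within ±3
Monte-Carlo standard errors of the life-table values — at the scale used
(50,000 initial members, 20 years, 20 seeds) that is a few-percent-level
tolerance on T2DM and a tighter-than-Poisson check on QALYs.

## Economics

Utilities are baseline-by-age/sex (0.95/0.94 at 30, −0.0018 per year of
age) minus additive decrements for excess BMI above 25 (0.006 per
kg/m²), T2DM (0.05), CHD (0.06) and stroke (0.12), clamped to [0, 1];
additive-then-clamp is the convention for regression-based decrements.
Costs per prevalent case-year (T2DM €3,000, CHD €2,500, stroke €5,000)
get an incident-year surcharge on top (€1,000/€8,000/€15,000) — the
incident year costs prevalent + surcharge, a documented resolution of an
ambiguity in how acute-event costs stack.  A background other-care cost
(€2,000 per person-year alive) makes longer lives more expensive, which
is why "other" cost categories move against the disease-specific savings.
The societal perspective adds T2DM self-management (€600/yr) and
health-service time (€750/yr), other health-service time (€200 per
person-year), sick leave for prevalent T2DM/stroke below 65
(€900/€300/yr), early-retirement lump sums per incident case below 65
(€20,000/€25,000), and premature-death costs valuing every wage year
from death to 65 at €45,000 (pure human capital; no friction-cost
option).  All flows discount at 1/(1+r)^t with r = 0.03 and t = 0
undiscounted; no half-cycle correction in a discrete annual model.  All
monetary and utility magnitudes are placeholders of plausible German
order, clearly configuration rather than estimates.

ICERs follow the dominance rule: cost savings with health gains are
"Dominant" (no trade-off exists), health losses at non-negative cost are
"Dominated", otherwise €/QALY; a (0, 0) contrast is flagged "Undefined".

## Uncertainty

Each PUA iteration draws parameters (second order: elasticities and
pass-through normal with CI-derived SEs, RRs log-normal, β normal
truncated at 0, cost and utility-decrement multipliers normal(1, 0.1)
truncated at 0, truncations logged) and runs a paired simulation with a
fresh first-order seed (new population sample and event draws).  Draws
are shared across scenarios within an iteration so scenario contrasts
difference out parameter noise.  Intervals are percentile (2.5/50/97.5),
not normal-approximation.  The reference setting is 500 iterations; the
package default is 50, raised via `n_iter`/`--iters` — results at 50
iterations carry visibly wider Monte-Carlo noise on the interval
endpoints.

## Problem sizes and determinism

Everything is deterministic given explicit integer seeds (NumPy
PCG64).  The test suite runs end-to-end checks at the scales the package
itself is designed for: demand recovery on 20 replicate panels of 5,000
households; cross-model agreement and epidemiological consistency on a
population of 50,000 initial members (≈72,000 with entrants) over 20
years with 20 replicate arm seeds; engine property tests on 4,000
members.  A paired 50,000-member arm comparison takes on the order of a
second, so the full pipeline is interactive at analysis scale.

## What passing tests do and do not show

The generators reproduce the *structure* real inputs would have (mixture
intakes, consistent illness–death epidemiology, AIDS-generated budget
shares), so green tests demonstrate that the machinery — estimation,
operators, engines, accounting — is correct and internally consistent.
They do not validate the placeholder parameter values against Germany or
any other population: absolute QALY and cost magnitudes from the default
configuration are illustrative only.  Known limitations, in addition:
no within-person BMI trajectories; no elasticity heterogeneity by
age/sex; no direct effects of fruit juice; no children/adolescents,
migration, disease recurrence or severity staging; no tax revenue or
policy implementation/reformulation costs; cumulative lifetime sugar
exposure is not modelled.
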