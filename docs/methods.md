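# Model and methods

This note documents the scientific content of `copdsim`: the disease and
care-cascade model, its parameters and their defaults, the synthetic cohort
generator, the economic accounting, numerical conventions, the genuinely
open design choices we had to settle, and known limitations.

## Disease model

COPD is represented by a single continuous state, lung function as a
fraction of the age/sex reference (FEV1 % predicted), mapped to GOLD
severity stages at ≥80% (1), 50–79% (2), 30–49% (3) and <30% (4). Time
advances in 3-month cycles from cohort entry (ages 35–80) to death or a
110-year absorbing cap.

**Lung-function decline.** Each patient cycle draws an annual decline from
the stage-specific normal (μ = 40, 60, 56, 34 ml/yr; σ = 5), floored at
zero (decline is a loss process), multiplied by 1.957 if an exacerbation
occurred within the previous 12 months, reduced by the absolute treatment
effect, floored at zero again, and scaled to the quarter. FEV1 in liters
falls by that amount while the healthy reference falls along its own age
slope, so the % predicted update is

`f ← min(f, (f·P(a) − Δml/1000) / P(a + Δt))`

with `P` the linear-in-age reference (defaults: men 3.80 L at 35, −28
ml/yr; women 2.80 L, −22 ml/yr — mid-range of published Chinese reference
equations). The outer `min` enforces the modelling commitment that
treatment can halt but never reverse disease: % predicted is non-increasing
and stage non-decreasing for every patient. Untreated patients never hit
the cap because every stage's decline mean exceeds the reference slope.

**Exacerbations.** Two independent Poisson processes per patient cycle
(non-severe 0.71/1.01/1.39/1.82 per year by stage; severe
0.11/0.16/0.22/0.28), scaled by the treated relative risk. An event resets
the 12-month accelerated-decline window; events do not stack.

**Mortality.** Background annual death probabilities come from the packaged
life table, converted to a constant hazard `−ln(1−q)`. Patients multiply
the hazard by the stage hazard ratio (1.2/1.6/2.7/2.7) and, if treated, the
treatment's mortality relative risk. A patient death is labelled
COPD-attributed with the excess-hazard fraction `(HR·rr − 1)/(HR·rr)` —
the model's operational definition of a COPD-related death.

**Life table.** The packaged fixture
(`data/life_table_china_synthetic.csv`) is *synthetic*: one Gompertz hazard
per sex over ages 35–100, calibrated so remaining life expectancy at 35 is
42.3 years (men) and 47.5 years (women), matching China 2020 period life
tables. Ages beyond 100 reuse the terminal row (q = 0.7/yr for men), which
terminates the horizon well before the 110-year cap.

## Care cascade

Diagnosis can only happen through confirmatory spirometry, treated as a
perfect gold standard. Three routes:

- **Symptom-driven (status quo).** Undiagnosed patients are diagnosed each
  cycle with a stage-specific probability calibrated (see below) so that
  cross-sectional awareness among living patients tracks the observed
  profile 0.63 / 2.00 / 12.87 / 21.04 % by stage.
- **One-step screening.** The COPD-SQ questionnaire (sens 0.57, spec 0.82)
  is offered to everyone alive and not already diagnosed.
- **Two-step screening.** Questionnaire-positives take a portable
  spirometer test (sens 0.85, spec 0.85) in the same visit; composite
  sensitivity 0.4845, specificity 0.973.

Screen-positives reach confirmatory spirometry with probability 0.40
(incomplete linkage to care); false positives incur the test cost and
return unlabelled to the pool. Frequencies: one-time (cycle 0) or every
1/2/5/10 years starting at year 0.

**Treatment.** Newly diagnosed patients start one of five long-acting
archetypes with probability 0.30; decliners are not re-approached until
their stage changes; treated patients switch archetypes when their stage
changes (stage-specific mix, re-drawn, treatment clock reset). Archetypes
are spaced evenly across the published effect ranges (decline reduction
73–201 ml/yr, exacerbation RR 0.92–0.62, mortality RR 0.99–0.71, monthly
cost $20.21–104.58), paired rank-wise so stronger therapy costs more; the
default mix shifts toward stronger archetypes at higher stages. The decline
reduction applies only for the first 12 months on the current archetype —
the limit of the supporting clinical evidence — while the exacerbation and
mortality relative risks persist while on treatment. We considered the
alternative reading in which the decline effect renews indefinitely under
continuous therapy and rejected it: mid-range archetypes (reduction ≥ the
decline mean) would then freeze progression permanently, inflating the
per-person QALY gain of annual screening several-fold beyond any published
estimate for comparable cascades.

**Calibration.** `calibrate_symptom_diagnosis` bisects each stage's
per-cycle probability with the full status-quo simulator as the forward
model (window-averaged cross-sectional awareness over the second half of a
10-year run; two outer passes absorb cross-stage interaction). The frozen
defaults (2.20e-4, 2.93e-4, 9.38e-3, 2.34e-3 per cycle) came from a
30,000-person calibration, reproduce the awareness profile within ~7%, and
are deliberately *not* monotone in stage: stage-4 awareness is mostly
inherited from patients diagnosed at stage 3 who progressed, so the
residual stage-4 hazard needed is small.

## Cohort generator

`generate_cohort` is the synthetic-data module and defines the reference
conditions: ages drawn uniformly within five bands weighted by China 2020
census shares (0.130/0.272/0.293/0.194/0.111 for 35–39/40–49/50–59/60–69/
70–80), per-band male fractions from the census, COPD assigned by age/sex
prevalence (e.g., 27.08% for men 60–69), initial FEV1 % predicted from
truncated normals (men N(0.797, 0.206²), women N(0.835, 0.206²), truncated
to [0.05, 1.3]), initial awareness by stage, and a 30% treatment-uptake
draw for the initially diagnosed. Incident cases draw from the incident
distributions (men N(1.014, 0.0906²) — the printed male σ of 0.906 is
treated as a decimal slip, as it would put most draws outside physiologic
range — women N(1.034, 0.107²)) and enter mid-cycle, accruing at their
pre-conversion state until the next cycle. Ages beyond 80 reuse the last
band's prevalence/incidence. The generator does **not** emulate smoking
dynamics, geography, household structure, or secular trends; tests passing
against it validate internal consistency of the model, not real-world
forecasting skill.

## Economics

Utilities: an age-band baseline for the general population (0.956/0.946/
0.928/0.910/0.874 for 35–44/45–54/55–64/65–74/75+, Chinese EQ-5D norms);
COPD patients use stage multipliers normalized so the 65–74 reference band
reproduces the published absolute values 0.806/0.767/0.704/0.616 (an
absolute mode is available by flag). Exacerbations subtract 0.010
(non-severe) / 0.040 (severe) from the cycle's weight per event; the weight
is floored at zero. Persons dying within a cycle accrue half the cycle's
utility and time-based costs.

Costs (2022 USD, payer perspective), six categories: screening
(questionnaire $0.72/test, spirometer $2.90/test, program setup $4.00
charged once per person ever screened), diagnosis (confirmatory spirometry
$26.93), maintenance ($7.66/24.25/34.56/54.04 per month by stage, charged
to **all** prevalent patients), treatment (archetype monthly cost),
exacerbation ($68.24 / $2987.06 per event), and a complication hook
(default $0/month; configurable for, e.g., pneumonia costing). Two of these
conventions deserve justification because the published table is ambiguous:

- *Maintenance pool.* Charging maintenance only to diagnosed patients makes
  each diagnosis switch on a lifetime cost stream, which is an order of
  magnitude too large to be consistent with the published incremental costs
  of screening policies, and leaves the status-quo cost composition short
  of its published maintenance share. The default therefore charges all
  prevalent patients (claims for respiratory care do not require the
  patient to know the diagnosis); the stricter mode is a flag.
- *Setup cost.* Charged per round, the screening category would exceed the
  published "<2% of total cost" bound for annual policies by 2–3×; charged
  once per person it sits near 1%. Per-round charging remains a flag.

Both QALYs and costs are discounted at 3%/yr with the factor `1.03^(−t)`
evaluated at each cycle's midpoint; no half-cycle correction on state
membership.

## Engine and randomness

Within-cycle order: screening → symptom diagnosis → treatment
(re)assignment → incidence → exacerbations → decline & restaging → death →
accrual. Every stochastic process draws from a Philox stream keyed by
`(master seed, cycle, process id)` and indexed by person, so policy arms
under one seed are exactly coupled (common random numbers); exacerbation
counts use the Poisson inverse CDF on a per-person uniform so the coupling
survives treated-vs-untreated rate differences. An independent-streams mode
derives a fresh master seed per policy.

## Decision-analytic layer

ICERs are Δcost/ΔQALY with explicit dominance verdicts instead of division
by non-positive QALY differences. The frontier removes strictly dominated
policies (strictly more QALYs at no greater cost), then iteratively removes
extended-dominated ones (incremental ICER at least the next segment's),
leaving the lower-left convex hull with strictly increasing ICERs; tests
verify equivalence with a brute-force convex-blend oracle. "Most
cost-effective at a willingness-to-pay" is the frontier policy with the
largest QALYs whose frontier ICER does not exceed the threshold (default
WTP $38,441/QALY, 3× China 2022 GDP per capita). PSA draws each uncertain
parameter from beta (probabilities, utilities), gamma (costs, rates, hazard
ratios, clipped at 1) or normal (effect sizes) distributions with sd = 20%
of the mean by default, regenerates the cohort, and re-simulates all
policies per replicate; CEACs report the probability of maximizing net
monetary benefit, with ties split equally.

## Numerical conventions and problem sizes

Rate→probability conversions use the constant-hazard transform
`1 − exp(−r·Δt)`; annual probabilities compound exactly over four quarters.
Truncated-normal and Poisson draws go through inverse CDFs for coupling and
determinism. Reported analyses use n = 100,000 persons with three seeds
(Monte Carlo error on per-person QALYs ≈ 0.01; common random numbers make
small policy contrasts resolvable at this size); examples use 2,000–20,000
for speed. The calibration default budget is 30,000 persons over 10 years.

## Known limitations

- **Event-scale sensitivity.** Taking the published prevalence *and*
  incidence at face value under a China-calibrated life table yields ≈5
  COPD patient-years per cohort member over the lifetime horizon (≈2.2 from
  prevalent cases, ≈2.9 from incident cases — the male incidence of
  5,056/100,000/yr above age 70 converts most surviving susceptible men).
  Quantities proportional to patient exposure — total cost, total
  exacerbation and COPD-death counts, and absolute screening effects —
  scale with this exposure, and the implementation reports them about
  twofold above published point estimates whose inputs pooled patient
  exposure differently; ratio- and percentage-type outputs (ICERs, averted
  percentages, cost shares, frontier structure) are insensitive to it and
  reproduce closely. The tests encode both groups at their stated
  tolerances rather than adjusting inputs to split the difference.
- No smoking-status dynamics, treatment non-adherence, societal-perspective
  costs, or symptom-level treatment tailoring; the complication cost hook
  defaults to zero.
- The cohort is closed (no births or migration); screening policies are
  one-size-fits-all across age and risk groups.
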