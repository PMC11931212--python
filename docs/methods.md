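# Methods

## Model structure

The model is a prevalence-based Markov state-transition cohort model with
annual cycles. States describe smokeless-tobacco (ST) use, not disease:
never user, current user, former user in year *t* since quitting
(*t* = 1..10, tunnel states that can only be occupied for one cycle), a
long-term former state (10+ years), and dead. Each (sex, 5-year entry
band) cohort starts distributed over the living states according to the
observed never/current/former prevalence, with entering former users
spread uniformly over tunnel years 1–10 by default (the time-since-quit
composition of former users is not observable in cross-sectional
surveys; the split is configurable).

Within a cycle, death is resolved first at the status-specific
probability of the occupant's exposure class; behaviour change applies to
survivors: never → current with the initiation probability, current →
former-year-1 with the quit probability, former-year-*t* → current with
the relapse probability *r(t)* (otherwise mandatory progression to year
*t*+1, or to the long-term state after year 10). Resolving death first
keeps all-cause mortality conservation exact under the apportionment
below. No half-cycle correction is applied: the model is a plain
annual-cycle prevalence design, and all quantities accrue to the alive
mass at cycle start.

Cohorts run from their entry age (band lower bound) to age 89; the cycle
at 89 is the last one counted.

## Exposure classes and apportionment

For risk purposes the living states collapse to five exposure classes:
never, current, former 0–4 years (tunnel years 1–5), former 5–10 years
(tunnel years 6–10), former 10+ years. Given a population rate *p*
(all-cause mortality from the life table, or a disease prevalence),
relative effects *m_k* versus never users and exposure shares *s_k*, the
class-specific rates are

    r_never = p / Σ_k s_k m_k ,   r_k = m_k r_never ,

so Σ_k s_k r_k = p exactly. This conservation is the module's defining
contract: the model never creates or destroys deaths or disease relative
to the inputs, it only redistributes them across use states. Rates are
capped at 1 with a logged warning so extreme sensitivity-analysis draws
cannot produce invalid probabilities. The published odds ratios are
applied directly as rate ratios in this apportionment; for diseases at
the prevalences involved the distinction is second order.

Two assumptions shape the effects: ST carries no excess risk below age
35 (all multipliers are 1 there), and risk returns to the never-user
level ten years after quitting (the former-10+ multiplier is pinned at
exactly 1 and validated as such).

Mortality apportionment uses, each cycle, the *cohort's own* alive
exposure shares, so the share-weighted death probability equals the
life-table value whatever the cohort composition. Disease apportionment
in the status-quo scenario likewise uses the cohort's shares; for
attribution sub-cohorts the *full cohort's* shares are reused so the
decomposition by entry state is exact (see below).

## Scenarios and attributable burden

The status-quo scenario applies the calibrated behaviour dynamics. The
no-ST counterfactual keeps the whole cohort in the never state with
never-user mortality and never-user disease prevalence, both derived by
apportioning the population inputs over the *observed population*
exposure mix at each age (banded prevalence, constant within band,
clamped beyond the oldest band). Deriving the counterfactual from the
observed mix rather than from the cohort's trajectory keeps the two
scenarios consistent: when observed use is zero, or when all multipliers
are 1, the scenarios coincide and attributable burden is exactly zero.
A config flag (`no_st_mortality = "population"`) switches the
counterfactual to population mortality instead, since the original
choice is not observable; never-user mortality is the default because
the counterfactual population is unexposed.

Outcomes per cohort member: discounted life years (alive fraction per
cycle), discounted YLD (disease prevalence × disability weight, additive
across diseases in the absence of comorbidity data), and discounted
treatment costs (annual cost per prevalent cancer case; stroke cost
mixes first-year and subsequent-year cases through the incident
fraction). Attributable burden is the scenario difference; DALYs averted
= life years gained + YLD averted. Years of life lost are reported as
discounted ΔLY — in a scenario-difference design this coincides with
YLL. Both costs and outcomes are discounted at 3% per annum (default),
with *t* = 0 at cohort entry.

Attribution by entry state propagates the entry-never/current/former
sub-cohorts through the full cohort's per-cycle transition matrices
(linearity of the Markov update makes the weighted sum of sub-traces
equal the full trace exactly) and costs each against the shared
always-never baseline; the entry-share-weighted contributions therefore
reconstruct the full-cohort attributable cost to rounding error.

## Calibration of behaviour probabilities

Cross-sectional banded prevalence is read longitudinally (synthetic
cohort assumption): the model seeks constant-within-band annual
initiation and quit probabilities such that a cohort stepped five cycles
forward lands on the next band's observed never and former shares.

`calibrate_initiation` solves a two-compartment (never/ever) forward
model per band with differential survival, bracketed root-finding in
[0, 1]. `calibrate_quit` chains the full 14-state vector across bands so
the tunnel composition evolves consistently, and root-finds the quit
probability per band given initiation and relapse.
`calibrate_schedule` refines both by per-band fixed-point iteration on
the full state vector until both targets are met to ~1e-13, which makes
the calibration an exact inverse of the cohort engine: schedules that
generated synthetic prevalence through the engine are recovered to
better than 1e-6, and the calibrated model reproduces its input
prevalence table at every band boundary.

Where no root exists in [0, 1] the probability is clamped with a logged
warning — e.g. when the observed former share at the oldest band sits
slightly below what pure tunnel aging produces, quitting clamps to 0 and
the projection overshoots by well under 0.1 percentage points on the
packaged fixtures. Initiation and quitting above the oldest observed
band are held at the last band's values.

Relapse is not identifiable from a single cross-section; the default
schedule declines geometrically over tunnel years 1–10
(0.15 × 0.65^(t−1)) with zero relapse after ten years, and is
configurable/replaceable from CSV. Relapse must be non-increasing in
time since quitting.

## Parameters

| Parameter | Default | Notes |
|---|---|---|
| discount rate | 0.03 / year | applied to costs and outcomes alike |
| horizon age | 89 years | data above this age too uncertain |
| cycle length | 1 year | fixed |
| minimum risk age | 35 years | no excess risk below |
| entry bands | 15–19 … 70–74 | 5-year bands, both sexes |
| PSA draws | 5000 | config default; callers pass the draw count explicitly |
| incident stroke fraction | 0.10 | Beta(5, 45) |
| former-user entry split | uniform over tunnel years 1–10 | configurable |

Relative effects (current / former 0–4y / former 5–10y, versus never
users): mortality 1.25/1.09/1.02; oral cancer 5.55/2.61/1.45; pharyngeal
cancer 2.69/1.56/1.16; esophageal cancer 3.17/1.77/1.21; stroke
1.37/1.13/1.04; all former-10+ effects are 1. Effects are lognormal with
the packaged log-means and log-SEs. Disability weights per prevalent
case are Beta(50w, 50(1−w)) by disease and broad age band (15–49, 50–69,
70+); the printed table lists one sex per disease block, and the same
weights are applied to both sexes here. One annual cancer cost applies
to all three cancers per country group (India/Pakistan share a cost set;
Bangladesh has its own), as the source table provides a single cancer
cost row.

Cost uncertainty: the printed gamma parameterizations are numerically
inconsistent with the USD point estimates (their implied means sit on an
unstated original scale), so the default is Gamma(shape 100,
scale = point/100) — mean equal to the point estimate, 10% coefficient
of variation. The verbatim printed parameters remain loadable with
`gamma_mode="table1"`, with the caveat that draws are then not on the
USD scale.

## Probabilistic sensitivity analysis

All uncertain parameters are sampled independently per draw; the
deterministic pipeline is re-run and 95% credible intervals are taken as
empirical 2.5/97.5 percentiles. Structural constraints are re-enforced
by resampling: effect triples must satisfy current ≥ former 0–4 ≥ former
5–10 ≥ 1, and the prevalent stroke cost may not exceed the incident
cost. The truncation raises the mean of the more uncertain effects
slightly above the raw lognormal mean (about 3% for the stroke effect);
the tests quantify this against a rejection-sampling oracle.
Behaviour probabilities (initiation/quit/relapse) are held at their
calibrated values during PSA — no uncertainty distributions are
published for them — which understates total uncertainty; this is a
known limitation. The whole PSA is reproducible from a single seed.

## Synthetic data generator

`make_synthetic_bundle(seed)` emulates the model's data sources: a
Gompertz life table (q(15) ≈ 0.0012–0.0016 rising ~8%/year, capped at
0.7); never-user share declining smoothly with age (0.95 → ~0.52 for
men, 0.97 → ~0.75 for women) and former share rising toward ~0.30/~0.12,
making current use hump-shaped with a middle-age peak and men using more
than women; logistic age-increasing disease prevalence (cancers capped
near 0.2–0.4%, stroke near 6%, male excess 1.15×); populations of a few
million per band declining ~4.5%/band with age; and the packaged
effect/weight/cost defaults. The seed jitters curve *parameters* (±3–10%)
rather than individual bands, so the monotonicities the calibration
relies on hold for every seed.

What the generator does not emulate: survey sampling noise and design
effects, non-monotone cohort effects in use prevalence (e.g. period
effects from past policy changes), ST product-type heterogeneity,
between-disease correlation, and country-specific age patterns. Passing
tests therefore demonstrate the correctness of the machinery (balance,
conservation, calibration inverse, decomposition, reproducibility) and
plausible magnitudes — not agreement with any particular country's data.
Published input tables can be substituted via the documented CSV bundle
format, after which the same pipeline applies verbatim.

## Numerical choices

- Root-finding: Brent's method on [0, 1], xtol 1e-14; calibration
  fixed-point stops when both share targets are within 1e-13.
- Transition-matrix rows sum to 1 to better than 1e-12 by construction;
  traces are validated for mass conservation (1e-10), non-negativity and
  monotone dead occupancy.
- Apportionment conservation holds to ~1e-16 per cycle.
- Exposure shares fall back to the observed population mix if the alive
  mass underflows (never triggered at the packaged mortality levels,
  where q is capped at 0.7 < 1).
- Bundle CSV IO is lossless (floats written as shortest round-trip
  representation and re-read with exact parsing) and byte-deterministic,
  so identical inputs yield identical files and manifest digests.
- Banded inputs are expanded to integer ages by constant interpolation
  within band — the simplest faithful reading of banded survey/GBD
  tables.

## Problem sizes

The packaged configuration runs 24 cohorts (2 sexes × 12 entry bands) of
up to 75 annual cycles each; the test suite and the acceptance script
use a 200-draw PSA over two cohorts and 100k-draw distribution checks,
sizes chosen to exercise every code path at interactive speed while
keeping Monte-Carlo error far below the asserted tolerances.

## Known limitations

- The synthetic-cohort calibration attributes all cross-sectional age
  differences to aging; real cohort and period effects would bias the
  calibrated probabilities.
- Disease recovery is not modelled explicitly; it is inherited through
  the age/sex prevalence inputs.
- Disease prevalences are treated as independent across diseases and
  disutility as additive.
- The former 0–4/5–10 year risk strata are applied as two steps, not
  interpolated by single year of quitting.
- Costs exclude indirect, caregiver and productivity losses (healthcare
  perspective only); currency conversion/inflation is out of scope —
  inputs are assumed already in USD.
- Behaviour probabilities carry no uncertainty in the PSA.
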