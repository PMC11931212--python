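# astramod

A Markov state-transition cohort model estimating the lifetime healthcare
costs, life years and DALYs attributable to smokeless tobacco (ST) use,
by 5-year age–sex cohorts, under the current policy status quo versus a
counterfactual in which nobody consumes ST.

The package is aimed at health economists and tobacco-control researchers
who need per-cohort lifetime burden estimates from routinely available
inputs: GATS-style never/current/former use prevalence by 5-year band,
UN-style life tables, GBD-style prevalence of four ST-associated diseases
(oral, pharyngeal and esophageal cancer, and stroke), plus relative
effects, disability weights and unit treatment costs (packaged defaults
included). A synthetic-bundle generator produces statistically plausible
country inputs so everything runs without any external data.

## The model

Cohort members occupy one of 14 mutually exclusive states: never user,
current user, ten former-user tunnel states (one per year since
quitting), a long-term former state (10+ years) and dead. Cycles are
annual; death is an absorbing state resolved first within each cycle.
Disease is not a state: each cycle, population disease prevalence
*p* is apportioned across exposure classes *k* (never, current, former
0–4y, 5–10y, 10+y) using relative effects *m<sub>k</sub>* and the alive
exposure shares *s<sub>k</sub>*:

    r_never = p / Σ_k s_k m_k ,   r_k = m_k r_never ,

so the share-weighted mean reproduces *p* exactly. The same apportionment
anchors status-specific mortality to the life table. Risk returns to the
never-user level ten years after quitting, and ST is assumed to carry no
excess risk below age 35.

Initiation and quit probabilities are calibrated so that a cohort stepped
through the model reproduces the observed cross-sectional prevalence of
the next age band; relapse declines with time since quitting. Burden is
the scenario difference — life years gained, YLD averted (prevalence ×
disability weight, additive across diseases), DALYs averted = ΔLY + ΔYLD,
and treatment costs averted — discounted at 3% per annum, run to age 89,
and scaled by cohort population. Parameter uncertainty is propagated by
Monte Carlo (lognormal effects, beta weights and fractions, gamma costs)
with percentile 95% credible intervals.

## Worked example

```python
import astramod as am

bundle = am.make_synthetic_bundle(1)          # synthetic country inputs
schedule = am.calibrate_schedule(bundle)      # initiation/quit calibration

result = am.burden_for_cohort(bundle, "male", (15, 19), schedule)
print(f"life years gained:   {result.ly_gained:.3f}")
print(f"DALYs averted:       {result.dalys_averted:.3f}")
print(f"cost saved (USD):    {result.cost_averted:.2f}")

att = am.attribute_by_entry_state(bundle, "male", (15, 19), schedule)
print(f"share borne by entry never-users: {att.shares['never']:.2f}")

per_cohort, totals = am.aggregate_country(bundle, schedule)
print(f"country total attributable cost: "
      f"{totals['cost_averted_total']/1e9:.2f} billion USD")
```

prints

```
life years gained:   0.165
DALYs averted:       0.166
cost saved (USD):    16.70
share borne by entry never-users: 0.91
country total attributable cost: 1.15 billion USD
```

Read: if ST were eliminated, an average 15-year-old male in this
synthetic country would gain 0.165 discounted life years, avert 0.166
DALYs and save US$16.70 in lifetime treatment costs; 91% of the young
cohort's attributable cost is borne by those who do not yet use ST at 15
but are projected to start later. Summing population-scaled results over
all 24 age–sex cohorts gives the country total.

The same workflow is available from the shell:

```sh
astramod synth --seed 1 --out bundle/
astramod calibrate --bundle bundle/ --out schedule.csv
astramod run --bundle bundle/ --schedule schedule.csv --out reports/
astramod psa --bundle bundle/ --schedule schedule.csv --draws 200 --seed 1 --out psa/
```

## Layout

- `astramod.inputs` — validated input types and lossless CSV/YAML bundle IO
- `astramod.synthetic` — seeded synthetic country bundles
- `astramod.defaults` — packaged relative effects, weights, costs, distributions
- `astramod.risk` — exposure-class apportionment and attributable fractions
- `astramod.transitions` — transition matrices and initiation/quit calibration
- `astramod.engine` — the annual-cycle cohort engine
- `astramod.burden` — discounting, costs, YLD/DALYs, attribution, aggregation
- `astramod.psa` — parameter sampling and credible intervals
- `astramod.cli` — the `astramod` command

See `docs/methods.md` for the model's assumptions, parameters and
limitations.
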