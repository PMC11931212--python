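"""Discounted lifetime burden accounting.

Each cycle, the population prevalence of the four modelled diseases is
apportioned across exposure classes (conserving the population value
among the alive), then costed per prevalent case and weighted by
disability to give years lived with disability (YLD).  Life years count
the alive fraction at cycle start.  All streams are discounted to cohort
entry.  The burden attributable to use is the scenario difference:
life years gained = no-use minus status quo; YLD and costs averted =
status quo minus no-use; DALYs averted = life years gained + YLD averted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bands import Band, format_band
from .inputs import CountryInputBundle
from .risk import DISEASES, effective_multipliers, status_specific_rate
from .states import CLASS_OF_STATE, DEAD, exposure_shares
from .engine import (
    CohortSpec,
    CohortTrace,
    population_exposure_shares,
    run_cohort,
    run_subcohorts_by_initial_state,
)
from .transitions import TransitionSchedule


@dataclass(frozen=True)
class ScenarioBurden:
    """Discounted lifetime totals per entering cohort member, one scenario."""

    life_years: float
    yld: float
    cost_by_disease: dict[str, float]

    @property
    def cost_total(self) -> float:
        return float(sum(self.cost_by_disease.values()))


@dataclass(frozen=True)
class BurdenResult:
    """Status-quo versus no-use burden for one (sex, entry band) cohort."""

    country: str
    sex: str
    entry_band: Band
    status_quo: ScenarioBurden
    no_st: ScenarioBurden

    @property
    def ly_gained(self) -> float:
        return self.no_st.life_years - self.status_quo.life_years

    @property
    def yld_averted(self) -> float:
        return self.status_quo.yld - self.no_st.yld

    @property
    def dalys_averted(self) -> float:
        return self.ly_gained + self.yld_averted

    @property
    def cost_averted(self) -> float:
        return self.status_quo.cost_total - self.no_st.cost_total

    def cost_averted_by_disease(self) -> dict[str, float]:
        return {
            d: self.status_quo.cost_by_disease[d] - self.no_st.cost_by_disease[d]
            for d in DISEASES
        }

    def scaled(self, population: float) -> dict[str, float]:
        """Population-scaled attributable burden."""
        return {
            "population": population,
            "ly_gained": self.ly_gained * population,
            "yld_averted": self.yld_averted * population,
            "dalys_averted": self.dalys_averted * population,
            "cost_averted": self.cost_averted * population,
        }


def discounted_total(series: np.ndarray, rate: float) -> float:
    """Present value at cohort entry: sum_t series[t] / (1 + rate)^t."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("discount rate must be in [0, 1)")
    series = np.asarray(series, dtype=float)
    t = np.arange(len(series))
    return float(series @ (1.0 + rate) ** (-t))


def cycle_disease_burden(
    occupancy_row: np.ndarray,
    bundle: CountryInputBundle,
    sex: str,
    age: int,
    shares: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, float]]:
    """Per-disease exposure-class prevalences for one cycle.

    Apportions each disease's population prevalence over the exposure
    classes using the supplied alive shares (defaults to the shares of
    the row itself).  Returns, per disease, the length-5 class
    prevalences and the alive-weighted mean — the latter equals the input
    population prevalence (conservation).
    """
    if shares is None:
        shares = exposure_shares(occupancy_row)
    alive = occupancy_row[:DEAD]
    alive_total = float(alive.sum())
    out: dict[str, tuple[np.ndarray, float]] = {}
    for disease in DISEASES:
        pop_prev = bundle.disease_prevalence.at_age(disease, sex, age)
        mult = effective_multipliers(
            bundle.risk_set, disease, age, bundle.config.min_risk_age
        )
        rates = status_specific_rate(pop_prev, shares, mult)
        mean = float(alive @ rates[CLASS_OF_STATE]) / alive_total if alive_total > 0 else 0.0
        out[disease] = (rates, mean)
    return out


def cycle_cost(
    per_class_prevalence: dict[str, np.ndarray],
    occupancy_row: np.ndarray,
    costs,
) -> float:
    """Treatment cost per entering cohort member accrued this cycle.

    Cancers cost their annual per-prevalent-case amount; stroke mixes
    first-year and subsequent-year costs via the incident fraction.
    """
    alive = occupancy_row[:DEAD]
    total = 0.0
    for disease, rates in per_class_prevalence.items():
        mass = float(alive @ np.asarray(rates)[CLASS_OF_STATE])
        total += mass * costs.cost_for(disease)
    return total


def cycle_yld(
    per_class_prevalence: dict[str, np.ndarray],
    occupancy_row: np.ndarray,
    weights,
    sex: str,
    age: int,
) -> float:
    """Years lived with disability accrued this cycle (additive across
    diseases)."""
    alive = occupancy_row[:DEAD]
    total = 0.0
    for disease, rates in per_class_prevalence.items():
        mass = float(alive @ np.asarray(rates)[CLASS_OF_STATE])
        total += mass * weights.weight(disease, sex, age)
    return total


def _accumulate(
    bundle: CountryInputBundle,
    sex: str,
    trace: CohortTrace,
    rates_source: CohortTrace,
) -> ScenarioBurden:
    """Lifetime discounted burden of ``trace``.

    Disease apportionment uses the exposure shares of ``rates_source``
    (the full status-quo cohort for status-quo and attribution runs; the
    observed population mix for the no-use counterfactual), so sub-cohort
    burdens decompose the full cohort's burden exactly.
    """
    cfg = bundle.config
    n = len(trace.ages)
    ly = trace.occupancy[:, :DEAD].sum(axis=1)
    yld = np.zeros(n)
    cost = {d: np.zeros(n) for d in DISEASES}
    for t in range(n):
        age = int(trace.ages[t])
        row = trace.occupancy[t]
        if not np.any(row[:DEAD] > 0):
            continue
        per_class = cycle_disease_burden(
            row, bundle, sex, age, shares=rates_source.shares[t]
        )
        alive = row[:DEAD]
        for disease, (rates, _) in per_class.items():
            mass = float(alive @ rates[CLASS_OF_STATE])
            yld[t] += mass * bundle.disability_weights.weight(disease, sex, age)
            cost[disease][t] = mass * bundle.costs.cost_for(disease)
    rate = cfg.discount_rate
    return ScenarioBurden(
        life_years=discounted_total(ly, rate),
        yld=discounted_total(yld, rate),
        cost_by_disease={d: discounted_total(cost[d], rate) for d in DISEASES},
    )


def _no_st_shares_trace(bundle: CountryInputBundle, sex: str, trace: CohortTrace) -> CohortTrace:
    """A shares table for the counterfactual: observed population mix."""
    shares = np.stack(
        [
            population_exposure_shares(bundle.use_prevalence, sex, int(age))
            for age in trace.ages
        ]
    )
    return CohortTrace(
        spec=trace.spec, ages=trace.ages, occupancy=trace.occupancy, shares=shares
    )


def burden_for_cohort(
    bundle: CountryInputBundle,
    sex: str,
    entry_band: Band,
    schedule: TransitionSchedule,
) -> BurdenResult:
    """Run both scenarios for one cohort and difference them."""
    sq_spec = CohortSpec(bundle.country, sex, entry_band, "status_quo")
    ns_spec = CohortSpec(bundle.country, sex, entry_band, "no_st")
    sq = run_cohort(bundle, sq_spec, schedule)
    ns = run_cohort(bundle, ns_spec, schedule)
    ns_rates = _no_st_shares_trace(bundle, sex, ns)
    return BurdenResult(
        country=bundle.country,
        sex=sex,
        entry_band=tuple(entry_band),
        status_quo=_accumulate(bundle, sex, sq, sq),
        no_st=_accumulate(bundle, sex, ns, ns_rates),
    )


@dataclass(frozen=True)
class EntryStateAttribution:
    """Attributable cost split by use state at cohort entry.

    ``attributable`` is each entry group's share-weighted contribution
    (per entering member of the full cohort); contributions sum to the
    full-cohort attributable cost.  ``shares`` is each group's fraction
    of the total, or None when the total is not positive.
    """

    attributable: dict[str, float]
    total: float
    shares: Optional[dict[str, float]]


def attribute_by_entry_state(
    bundle: CountryInputBundle,
    sex: str,
    entry_band: Band,
    schedule: TransitionSchedule,
) -> EntryStateAttribution:
    """Decompose attributable cost over entry-never/current/former groups.

    Each group is propagated through the full cohort's transition
    matrices and costed against its own always-never baseline, so the
    entry-share-weighted group costs reproduce the full-cohort
    attributable cost exactly.
    """
    spec = CohortSpec(bundle.country, sex, entry_band, "status_quo")
    full, traces, weights = run_subcohorts_by_initial_state(bundle, spec, schedule)
    ns = run_cohort(
        bundle, CohortSpec(bundle.country, sex, entry_band, "no_st"), schedule
    )
    ns_rates = _no_st_shares_trace(bundle, sex, ns)
    baseline_cost = _accumulate(bundle, sex, ns, ns_rates).cost_total

    attributable: dict[str, float] = {}
    for state in ("never", "current", "former"):
        weight = weights[state]
        if weight <= 0.0 or state not in traces:
            attributable[state] = 0.0
            continue
        group_cost = _accumulate(bundle, sex, traces[state], full).cost_total
        attributable[state] = weight * (group_cost - baseline_cost)
    total = sum(attributable.values())
    shares = {k: v / total for k, v in attributable.items()} if total > 0 else None
    return EntryStateAttribution(attributable=attributable, total=total, shares=shares)


def aggregate_country(
    bundle: CountryInputBundle,
    schedule: TransitionSchedule,
) -> tuple[pd.DataFrame, pd.Series]:
    """Population-scaled burden for every (sex, entry band) cohort.

    Returns the per-cohort table and the country totals (sums over
    strata, weighting per-individual results by cohort population).
    """
    rows = []
    for sex in bundle.config.sexes:
        for band in bundle.config.entry_bands:
            result = burden_for_cohort(bundle, sex, band, schedule)
            population = bundle.population.count(sex, band)
            rows.append(
                {
                    "country": bundle.country,
                    "sex": sex,
                    "entry_band": format_band(band),
                    "population": population,
                    "ly_gained_per_individual": result.ly_gained,
                    "yld_averted_per_individual": result.yld_averted,
                    "dalys_averted_per_individual": result.dalys_averted,
                    "cost_averted_per_individual": result.cost_averted,
                    "ly_gained_total": result.ly_gained * population,
                    "dalys_averted_total": result.dalys_averted * population,
                    "cost_averted_total": result.cost_averted * population,
                }
            )
    df = pd.DataFrame(rows)
    totals = df[
        ["population", "ly_gained_total", "dalys_averted_total", "cost_averted_total"]
    ].sum()
    totals["country"] = bundle.country
    return df, totals
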