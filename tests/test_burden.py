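"""Burden accounting: discounting, costs, YLD, scenario differences."""

import numpy as np
import pytest

import astramod as am
from astramod.burden import _accumulate  # noqa: F401  (used indirectly)
from astramod.defaults import default_costs, default_disability_weights
from astramod.engine import CohortSpec
from astramod.states import DEAD, N_STATES, NEVER


class TestDiscountedTotal:
    def test_entry_cycle_is_undiscounted(self):
        assert am.discounted_total([100.0], 0.12) == 100.0

    def test_two_cycles_at_three_percent(self):
        assert am.discounted_total([100.0, 100.0], 0.03) == pytest.approx(
            197.0874, abs=5e-5
        )

    def test_zero_rate_is_plain_sum(self):
        series = [1.0, 2.5, 3.25]
        assert am.discounted_total(series, 0.0) == pytest.approx(sum(series))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            am.discounted_total([1.0], 1.0)


class TestCycleCost:
    def test_stroke_cost_worked_example(self):
        # 0.01 prevalence, fully alive cohort, costs (821, 82), fraction 0.1
        costs = default_costs("india_pakistan")
        row = np.zeros(N_STATES)
        row[NEVER] = 1.0
        rates = {"stroke": np.full(5, 0.01)}
        expected = 0.01 * (0.1 * 821 + 0.9 * 82)
        assert am.cycle_cost(rates, row, costs) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.559, abs=1e-4)

    def test_zero_prevalence_costs_nothing(self):
        costs = default_costs()
        row = np.zeros(N_STATES)
        row[NEVER] = 1.0
        assert am.cycle_cost({d: np.zeros(5) for d in ("stroke", "oral_cancer")}, row, costs) == 0.0

    def test_cost_is_linear_in_unit_costs(self):
        row = np.zeros(N_STATES)
        row[NEVER] = 0.8
        rates = {"oral_cancer": np.full(5, 0.002), "stroke": np.full(5, 0.01)}
        base = default_costs()
        doubled = am.CostTable(
            annual_cancer_cost=2 * base.annual_cancer_cost,
            incident_stroke_cost=2 * base.incident_stroke_cost,
            prevalent_stroke_cost=2 * base.prevalent_stroke_cost,
            incident_stroke_fraction=base.incident_stroke_fraction,
        )
        assert am.cycle_cost(rates, row, doubled) == pytest.approx(
            2 * am.cycle_cost(rates, row, base)
        )


class TestCycleYld:
    def test_single_disease_worked_example(self):
        # prevalence 0.02 among a fully alive cohort, weight 0.164
        weights = default_disability_weights()
        row = np.zeros(N_STATES)
        row[NEVER] = 1.0
        yld = am.cycle_yld({"oral_cancer": np.full(5, 0.02)}, row, weights, "male", 40)
        assert yld == pytest.approx(0.02 * 0.164, abs=1e-12)

    def test_additive_across_diseases(self):
        weights = default_disability_weights()
        row = np.zeros(N_STATES)
        row[NEVER] = 1.0
        one = am.cycle_yld({"oral_cancer": np.full(5, 0.02)}, row, weights, "male", 40)
        two = am.cycle_yld({"stroke": np.full(5, 0.01)}, row, weights, "male", 40)
        both = am.cycle_yld(
            {"oral_cancer": np.full(5, 0.02), "stroke": np.full(5, 0.01)},
            row, weights, "male", 40,
        )
        assert both == pytest.approx(one + two, abs=1e-15)


class TestCycleDiseaseBurden:
    def test_unit_multipliers_leave_prevalence_unchanged(self, null_bundle, null_schedule):
        trace = am.run_cohort(
            null_bundle, CohortSpec("x", "male", (40, 44)), null_schedule
        )
        per = am.cycle_disease_burden(trace.occupancy[3], null_bundle, "male", 43)
        for disease, (rates, mean) in per.items():
            pop = null_bundle.disease_prevalence.at_age(disease, "male", 43)
            assert rates == pytest.approx([pop] * 5, abs=1e-15)
            assert mean == pytest.approx(pop, abs=1e-15)

    def test_below_minimum_age_equals_unit_multiplier_case(self, bundle, schedule):
        trace = am.run_cohort(bundle, CohortSpec("x", "male", (15, 19)), schedule)
        per = am.cycle_disease_burden(trace.occupancy[10], bundle, "male", 25)
        for disease, (rates, _) in per.items():
            pop = bundle.disease_prevalence.at_age(disease, "male", 25)
            assert rates == pytest.approx([pop] * 5, abs=1e-15)

    def test_conservation_at_every_cycle(self, bundle, schedule):
        trace = am.run_cohort(bundle, CohortSpec("x", "female", (15, 19)), schedule)
        for t, age in enumerate(trace.ages):
            per = am.cycle_disease_burden(
                trace.occupancy[t], bundle, "female", int(age), shares=trace.shares[t]
            )
            for disease, (_, mean) in per.items():
                pop = bundle.disease_prevalence.at_age(disease, "female", int(age))
                assert mean == pytest.approx(pop, abs=1e-10)


class TestBurdenForCohort:
    def test_null_model_attributable_burden_is_zero(self, null_bundle, null_schedule):
        """The central falsifiable contract: no excess risk, no burden."""
        for sex in ("male", "female"):
            for band in ((15, 19), (40, 44), (70, 74)):
                r = am.burden_for_cohort(null_bundle, sex, band, null_schedule)
                assert abs(r.ly_gained) < 1e-12
                assert abs(r.yld_averted) < 1e-12
                assert abs(r.cost_averted) < 1e-9

    def test_attributable_burden_positive_with_real_risks(self, bundle, schedule):
        r = am.burden_for_cohort(bundle, "male", (15, 19), schedule)
        assert r.ly_gained > 0
        assert r.yld_averted > 0
        assert r.cost_averted > 0
        assert r.dalys_averted == pytest.approx(r.ly_gained + r.yld_averted)

    def test_raising_mortality_multiplier_raises_life_years_gained(self, bundle, schedule):
        gains = []
        for mult in (1.1, 1.25, 1.6):
            table = {k: v.copy() for k, v in bundle.risk_set.table.items()}
            table["mortality"] = np.array([mult, 1.09, 1.02, 1.0])
            b = bundle.with_(risk_set=am.RiskSet(table))
            gains.append(am.burden_for_cohort(b, "male", (15, 19), schedule).ly_gained)
        assert gains[0] < gains[1] < gains[2]

    def test_results_are_deterministic(self, bundle, schedule):
        a = am.burden_for_cohort(bundle, "male", (15, 19), schedule)
        b = am.burden_for_cohort(bundle, "male", (15, 19), schedule)
        assert a.status_quo == b.status_quo and a.no_st == b.no_st

    def test_discounting_reduces_totals(self, bundle, schedule):
        r3 = am.burden_for_cohort(bundle, "male", (15, 19), schedule)
        b0 = bundle.with_(config=am.ModelConfig(discount_rate=0.0, rng_seed=1))
        r0 = am.burden_for_cohort(b0, "male", (15, 19), schedule)
        assert r3.status_quo.cost_total < r0.status_quo.cost_total
        assert r3.status_quo.life_years < r0.status_quo.life_years


class TestAttribution:
    def test_entry_state_decomposition_is_exact(self, bundle, schedule):
        for band in ((15, 19), (30, 34), (55, 59)):
            att = am.attribute_by_entry_state(bundle, "male", band, schedule)
            full = am.burden_for_cohort(bundle, "male", band, schedule)
            assert att.total == pytest.approx(full.cost_averted, abs=1e-9)
            assert sum(att.shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_young_cohort_never_users_bear_positive_burden(self, bundle, schedule):
        att = am.attribute_by_entry_state(bundle, "male", (15, 19), schedule)
        assert att.shares["never"] > 0

    def test_all_never_entry_band_gives_never_share_one(self, bundle, schedule):
        table = dict(bundle.use_prevalence.table)
        table[("male", (15, 19))] = (1.0, 0.0, 0.0)
        att = am.attribute_by_entry_state(
            bundle.with_(use_prevalence=am.UseStatePrevalence(table)),
            "male", (15, 19), schedule,
        )
        assert att.shares["never"] == pytest.approx(1.0)

    def test_universal_abstinence_leaves_nothing_to_attribute(self, bundle, schedule):
        prev = am.UseStatePrevalence(
            {(s, b): (1.0, 0.0, 0.0) for (s, b) in bundle.use_prevalence.table}
        )
        att = am.attribute_by_entry_state(
            bundle.with_(use_prevalence=prev), "male", (15, 19), schedule
        )
        assert att.total == pytest.approx(0.0, abs=1e-9)
        assert att.shares is None


class TestAggregateCountry:
    def test_totals_are_sum_over_strata(self, bundle, schedule):
        df, totals = am.aggregate_country(bundle, schedule)
        assert len(df) == 2 * len(bundle.config.entry_bands)
        assert totals["cost_averted_total"] == pytest.approx(
            df["cost_averted_total"].sum()
        )
        assert np.allclose(
            df["cost_averted_total"],
            df["cost_averted_per_individual"] * df["population"],
        )

    def test_doubling_population_doubles_totals(self, bundle, schedule):
        doubled = am.CohortPopulation(
            {k: 2 * v for k, v in bundle.population.table.items()}
        )
        _, t1 = am.aggregate_country(bundle, schedule)
        _, t2 = am.aggregate_country(bundle.with_(population=doubled), schedule)
        assert t2["cost_averted_total"] == pytest.approx(2 * t1["cost_averted_total"])

    def test_zero_population_gives_zero_totals(self, bundle, schedule):
        zero = am.CohortPopulation({k: 0.0 for k in bundle.population.table})
        _, totals = am.aggregate_country(bundle.with_(population=zero), schedule)
        assert totals["cost_averted_total"] == 0.0

    def test_zero_use_prevalence_knob_zeroes_attributable_burden(self):
        b = am.make_synthetic_bundle(5, {"st_prevalence_scale": 0.0})
        sched = am.calibrate_schedule(b)
        r = am.burden_for_cohort(b, "male", (15, 19), sched)
        assert abs(r.cost_averted) < 1e-9
        assert abs(r.ly_gained) < 1e-12
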