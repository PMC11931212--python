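"""Transition matrices and initiation/quit calibration."""

import numpy as np
import pytest

import astramod as am
from astramod.defaults import default_relapse, default_risk_set
from astramod.inputs import LifeTable, UseStatePrevalence
from astramod.states import CURRENT, DEAD, F1, FLONG, N_STATES, NEVER, exposure_shares
from astramod.transitions import (
    TransitionSchedule,
    _alive_shares,
    advance,
    build_transition_matrix,
    class_mortality,
)

RELAPSE = default_relapse()


def flat_life_table(q=0.0, horizon=89):
    arr = np.full(horizon - 15 + 1, q)
    return LifeTable(q={"male": arr, "female": arr.copy()}, age_min=15)


class TestBuildTransitionMatrix:
    def test_initiation_only_never_row(self):
        m = build_transition_matrix(0.1, 0.0, np.zeros(10), 0.0, np.zeros(5))
        expected = np.zeros(N_STATES)
        expected[NEVER], expected[CURRENT] = 0.9, 0.1
        assert m[NEVER] == pytest.approx(expected, abs=0)

    def test_pure_mortality_sends_q_to_dead(self):
        q = 0.03
        m = build_transition_matrix(0.0, 0.0, np.zeros(10), 0.0, np.full(5, q))
        for state in range(DEAD):
            assert m[state, DEAD] == pytest.approx(q)
            assert m[state].sum() == pytest.approx(1.0, abs=1e-15)
        # tunnel states advance to their successor
        for t in range(1, 10):
            assert m[F1 + t - 1, F1 + t] == pytest.approx(1 - q)
        assert m[F1 + 9, FLONG] == pytest.approx(1 - q)

    def test_dead_is_absorbing(self):
        m = build_transition_matrix(0.2, 0.3, RELAPSE, 0.01, np.full(5, 0.1))
        row = np.zeros(N_STATES)
        row[DEAD] = 1.0
        assert np.array_equal(m[DEAD], row)

    def test_rows_sum_to_one_across_full_grid(self, bundle, schedule):
        for sex in ("male", "female"):
            for age in range(15, 89):
                shares = np.array([0.4, 0.3, 0.1, 0.1, 0.1])
                qv = class_mortality(
                    bundle.life_table, bundle.risk_set, sex, age, shares, 35
                )
                m = build_transition_matrix(
                    schedule.i(sex, age), schedule.c(sex, age),
                    schedule.relapse, schedule.relapse_tail, qv,
                )
                assert np.abs(m.sum(axis=1) - 1.0).max() < 1e-12

    def test_out_of_range_probability_names_the_cell(self):
        with pytest.raises(ValueError, match="initiation"):
            build_transition_matrix(1.2, 0.0, np.zeros(10), 0.0, np.zeros(5))
        with pytest.raises(ValueError, match="relapse"):
            bad = np.zeros(10)
            bad[3] = -0.1
            build_transition_matrix(0.0, 0.0, bad, 0.0, np.zeros(5))


class TestScheduleContainer:
    def test_holds_last_value_above_grid(self, schedule):
        assert schedule.i("male", 200) == schedule.i("male", 88)

    def test_relapse_monotonicity_enforced(self):
        with pytest.raises(am.BundleValidationError, match="non-increasing"):
            TransitionSchedule(
                initiation={"male": np.zeros(74)},
                quit={"male": np.zeros(74)},
                relapse=np.linspace(0.0, 0.2, 10),
            ).validate()

    def test_frame_round_trip(self, schedule):
        again = TransitionSchedule.from_frame(schedule.to_frame())
        assert schedule.equals(again)


class TestCalibrateInitiation:
    def _prevalence(self, nevers):
        table = {}
        for k, never in enumerate(nevers):
            lo = 15 + 5 * k
            table[("male", (lo, lo + 4))] = (never, 1.0 - never, 0.0)
        return UseStatePrevalence(table)

    def test_flat_never_share_under_uniform_mortality_gives_zero_initiation(self):
        from astramod.defaults import null_risk_set

        prev = self._prevalence([0.8] * 12)
        i = am.calibrate_initiation(prev, flat_life_table(0.01), null_risk_set(), "male")
        assert np.abs(i).max() < 1e-12

    def test_closed_form_with_zero_mortality(self):
        # 0.80 -> 0.70 over one band: i = 1 - (0.70/0.80)^(1/5)
        prev = self._prevalence([0.8, 0.7] + [0.7] * 10)
        i = am.calibrate_initiation(prev, flat_life_table(0.0), default_risk_set(), "male")
        assert i[0] == pytest.approx(1.0 - (0.7 / 0.8) ** 0.2, abs=1e-12)

    def test_increasing_never_share_clamps_to_zero(self, caplog):
        prev = self._prevalence([0.7, 0.8] + [0.8] * 10)
        with caplog.at_level("WARNING"):
            i = am.calibrate_initiation(prev, flat_life_table(0.0), default_risk_set(), "male")
        assert i[0] == 0.0
        assert "clamped" in caplog.text

    def test_non_consecutive_bands_rejected(self):
        table = {("male", (15, 19)): (0.9, 0.1, 0.0), ("male", (25, 29)): (0.8, 0.2, 0.0)}
        with pytest.raises(am.BundleValidationError, match="consecutive"):
            am.calibrate_initiation(
                UseStatePrevalence(table), flat_life_table(), default_risk_set(), "male"
            )


class TestCalibrateQuit:
    def test_zero_former_everywhere_gives_zero_quit(self):
        table = {}
        for lo in range(15, 75, 5):
            table[("male", (lo, lo + 4))] = (0.7, 0.3, 0.0)
        prev = UseStatePrevalence(table)
        lt = flat_life_table(0.005)
        i = am.calibrate_initiation(prev, lt, default_risk_set(), "male")
        c = am.calibrate_quit(prev, np.zeros(10), lt, default_risk_set(), "male", i)
        assert np.abs(c).max() < 1e-12

    def test_doubling_relapse_raises_calibrated_quit(self, bundle):
        prev = bundle.use_prevalence
        lt, rs = bundle.life_table, bundle.risk_set
        i = am.calibrate_initiation(prev, lt, rs, "male")
        c_low = am.calibrate_quit(prev, RELAPSE, lt, rs, "male", i)
        c_high = am.calibrate_quit(prev, np.minimum(1.0, 2 * RELAPSE), lt, rs, "male", i)
        mask = (c_low > 0) & (c_low < 1)
        assert np.all(c_high[mask] >= c_low[mask])
        assert np.any(c_high[mask] > c_low[mask] + 1e-6)


class TestJointCalibration:
    def _engine_generated_prevalence(self, bundle, i_by_sex, c_by_sex, never0):
        """Forward-run the model and read banded shares: the recovery oracle."""
        table = {}
        for sex in ("male", "female"):
            v = np.zeros(N_STATES)
            v[NEVER] = never0[sex]
            v[CURRENT] = 1.0 - never0[sex]
            table[(sex, (15, 19))] = _alive_shares(v)
            for age in range(15, 74):
                shares = exposure_shares(v)
                qv = class_mortality(bundle.life_table, bundle.risk_set, sex, age, shares, 35)
                v, _ = advance(
                    v, i_by_sex[sex][age - 15], c_by_sex[sex][age - 15], RELAPSE, 0.0, qv
                )
                if (age + 1) % 5 == 0 and age + 1 < 75:
                    table[(sex, (age + 1, age + 5))] = _alive_shares(v)
        return UseStatePrevalence({k: tuple(map(float, v)) for k, v in table.items()})

    def test_parameter_recovery_from_engine_generated_prevalence(self, bundle):
        """Band-constant schedules that generated the data are recovered."""
        n_ages = 74
        i_true, c_true = {}, {}
        for s, (i0, c0) in (("male", (0.05, 0.04)), ("female", (0.02, 0.05))):
            iv, cv = np.zeros(n_ages), np.zeros(n_ages)
            for k, lo in enumerate(range(15, 70, 5)):
                iv[lo - 15 : lo - 10] = i0 * np.exp(-k / 4.0) + 0.002
                cv[lo - 15 : lo - 10] = c0 + 0.015 * np.sin(k + 1)
            iv[55:], cv[55:] = iv[54], cv[54]
            i_true[s], c_true[s] = iv, cv
        prev = self._engine_generated_prevalence(
            bundle, i_true, c_true, {"male": 0.92, "female": 0.97}
        )
        rec = am.calibrate_schedule(
            bundle.with_(use_prevalence=prev), relapse=RELAPSE, relapse_tail=0.0
        )
        for s in ("male", "female"):
            assert np.abs(rec.initiation[s][:55] - i_true[s][:55]).max() < 1e-6
            assert np.abs(rec.quit[s][:55] - c_true[s][:55]).max() < 1e-6

    def test_projected_prevalence_matches_observed_within_half_point(
        self, bundle, schedule
    ):
        """Self-consistency: the calibrated model reproduces its input table."""
        for sex in ("male", "female"):
            report = am.projected_prevalence(bundle, schedule, sex)
            assert report["max_abs_error"].max() < 0.005
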