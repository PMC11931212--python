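"""Annual-cycle cohort engine.

Runs one entering age-sex cohort forward to the horizon under either the
status-quo scenario (observed use dynamics; mortality apportioned across
exposure classes each cycle from the cohort's own alive composition, so
the share-weighted death probability always equals the life table) or
the no-use counterfactual (the whole cohort remains never users and dies
at the never-user rate implied by apportioning population mortality over
the observed population exposure mix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bands import Band, format_band
from .inputs import BundleValidationError, CountryInputBundle, UseStatePrevalence
from .states import (
    CURRENT,
    DEAD,
    F1,
    FLONG,
    N_STATES,
    NEVER,
    STATE_NAMES,
    exposure_shares,
)
from .transitions import TransitionSchedule, advance, class_mortality

SCENARIOS = ("status_quo", "no_st")

#: Default allocation of entering former users over time-since-quit:
#: uniform across tunnel years 1-10, nothing in the 10+ state.
DEFAULT_FORMER_SPLIT = np.array([0.1] * 10 + [0.0])


@dataclass(frozen=True)
class CohortSpec:
    """One cohort run: country, sex, entry band and scenario.

    ``initial_state`` optionally restricts the entering cohort to those
    who are never/current/former users at entry (normalised to mass 1),
    used for burden attribution by entry state.
    """

    country: str
    sex: str
    entry_band: Band
    scenario: str = "status_quo"
    initial_state: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.initial_state not in (None, "never", "current", "former"):
            raise ValueError("initial_state must be never/current/former or None")
        object.__setattr__(self, "entry_band", tuple(self.entry_band))


@dataclass(eq=False)
class CohortTrace:
    """State occupancy per cycle, plus the exposure shares used each cycle.

    ``occupancy[t]`` is the distribution over the 14 states at age
    ``ages[t]``; rows sum to the entering mass (1 for full cohorts).
    ``matrices[t]`` is the transition matrix applied between rows t and
    t+1 when the run was asked to keep them.
    """

    spec: CohortSpec
    ages: np.ndarray
    occupancy: np.ndarray
    shares: np.ndarray
    matrices: Optional[np.ndarray] = None

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, :DEAD].sum(axis=1)

    def validate(self, mass: float = 1.0, tol: float = 1e-10) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - mass) > tol):
            raise AssertionError("trace rows do not conserve mass")
        if np.any(self.occupancy < -1e-15):
            raise AssertionError("negative occupancy in trace")
        if np.any(np.diff(self.occupancy[:, DEAD]) < -1e-15):
            raise AssertionError("dead occupancy decreased")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df["alive"] = self.alive
        return df


def initial_state_vector(
    prevalence: UseStatePrevalence,
    sex: str,
    entry_band: Band,
    former_split: np.ndarray | None = None,
) -> np.ndarray:
    """Entry occupancy: never/current from the table, former spread over
    the tunnel and long-term states by the split rule."""
    if former_split is None:
        former_split = DEFAULT_FORMER_SPLIT
    former_split = np.asarray(former_split, dtype=float)
    if former_split.shape != (11,) or abs(former_split.sum() - 1.0) > 1e-9:
        raise ValueError("former_split must have 11 entries summing to 1")
    never, current, former = prevalence.at_band(sex, entry_band)
    v = np.zeros(N_STATES)
    v[NEVER] = never
    v[CURRENT] = current
    v[F1 : FLONG + 1] = former * former_split
    return v


def population_exposure_shares(
    prevalence: UseStatePrevalence,
    sex: str,
    age: int,
    former_split: np.ndarray | None = None,
) -> np.ndarray:
    """Observed population exposure-class shares at a single age.

    Banded never/current/former shares (constant within band, clamped
    beyond the oldest band) with the former mass allocated to the
    0-4y/5-10y/10+y strata by the entry split rule.
    """
    if former_split is None:
        former_split = DEFAULT_FORMER_SPLIT
    former_split = np.asarray(former_split, dtype=float)
    never, current, former = prevalence.at_age(sex, age)
    return np.array(
        [
            never,
            current,
            former * former_split[:5].sum(),
            former * former_split[5:10].sum(),
            former * former_split[10],
        ]
    )


def _never_user_mortality(bundle: CountryInputBundle, sex: str, age: int) -> float:
    """Never-user death probability implied by the observed population mix."""
    cfg = bundle.config
    if cfg.no_st_mortality == "population":
        return bundle.life_table.prob(sex, age)
    shares = population_exposure_shares(bundle.use_prevalence, sex, age)
    qv = class_mortality(
        bundle.life_table, bundle.risk_set, sex, age, shares, cfg.min_risk_age
    )
    return float(qv[0])


def run_cohort(
    bundle: CountryInputBundle,
    spec: CohortSpec,
    schedule: TransitionSchedule,
    *,
    keep_matrices: bool = False,
) -> CohortTrace:
    """Run one cohort from its entry age to the horizon.

    Status quo: starts from the observed entry distribution and applies
    the calibrated behaviour schedule with status-specific mortality
    recomputed each cycle from the cohort's own exposure shares.
    No-use counterfactual: the whole cohort stays in the never state with
    initiation forced to zero and never-user mortality.
    """
    cfg = bundle.config
    if tuple(spec.entry_band) not in {tuple(b) for b in cfg.entry_bands}:
        raise BundleValidationError(
            f"entry band {format_band(spec.entry_band)} not in config entry_bands"
        )
    entry_age = spec.entry_band[0]
    ages = np.arange(entry_age, cfg.horizon_age + 1)
    n_cycles = len(ages)
    for age in range(entry_age, cfg.horizon_age):
        schedule.i(spec.sex, age)  # raises on gaps below the grid

    if spec.scenario == "no_st":
        v = np.zeros(N_STATES)
        v[NEVER] = 1.0
    else:
        v = initial_state_vector(bundle.use_prevalence, spec.sex, spec.entry_band)
        if spec.initial_state is not None:
            keep = np.zeros(N_STATES)
            if spec.initial_state == "never":
                keep[NEVER] = v[NEVER]
            elif spec.initial_state == "current":
                keep[CURRENT] = v[CURRENT]
            else:
                keep[F1 : FLONG + 1] = v[F1 : FLONG + 1]
            total = keep.sum()
            if total <= 0:
                raise BundleValidationError(
                    f"no entering mass in state {spec.initial_state!r}"
                )
            v = keep / total

    occupancy = np.zeros((n_cycles, N_STATES))
    shares_used = np.zeros((n_cycles, 5))
    matrices = np.zeros((n_cycles - 1, N_STATES, N_STATES)) if keep_matrices else None
    occupancy[0] = v
    for t, age in enumerate(ages[:-1]):
        age = int(age)
        if spec.scenario == "no_st":
            q_never = _never_user_mortality(bundle, spec.sex, age)
            qv = np.full(5, q_never)
            shares = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
            v, m = advance(v, 0.0, 0.0, schedule.relapse, schedule.relapse_tail, qv)
        else:
            alive = v[:DEAD].sum()
            if alive > 1e-14:
                shares = exposure_shares(v)
            else:
                shares = population_exposure_shares(bundle.use_prevalence, spec.sex, age)
            qv = class_mortality(
                bundle.life_table, bundle.risk_set, spec.sex, age, shares, cfg.min_risk_age
            )
            v, m = advance(
                v,
                schedule.i(spec.sex, age),
                schedule.c(spec.sex, age),
                schedule.relapse,
                schedule.relapse_tail,
                qv,
            )
        shares_used[t] = shares
        occupancy[t + 1] = v
        if keep_matrices:
            matrices[t] = m
    # exposure shares at the final row (no transition follows)
    final_alive = occupancy[-1, :DEAD].sum()
    if spec.scenario == "no_st":
        shares_used[-1] = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    elif final_alive > 1e-14:
        shares_used[-1] = exposure_shares(occupancy[-1])
    else:
        shares_used[-1] = population_exposure_shares(
            bundle.use_prevalence, spec.sex, int(ages[-1])
        )
    return CohortTrace(
        spec=spec, ages=ages, occupancy=occupancy, shares=shares_used, matrices=matrices
    )


def run_subcohorts_by_initial_state(
    bundle: CountryInputBundle,
    spec: CohortSpec,
    schedule: TransitionSchedule,
) -> tuple[CohortTrace, dict[str, CohortTrace], dict[str, float]]:
    """Full-cohort trace plus normalised sub-traces by entry state.

    All sub-cohorts are propagated through the matrices of the full
    cohort run, so the entry-share-weighted sum of sub-traces equals the
    full trace exactly (linearity of the Markov update).
    Returns (full trace, {entry state: trace}, {entry state: weight}).
    """
    full_spec = CohortSpec(
        country=spec.country, sex=spec.sex, entry_band=spec.entry_band, scenario="status_quo"
    )
    full = run_cohort(bundle, full_spec, schedule, keep_matrices=True)
    never, current, former = bundle.use_prevalence.at_band(spec.sex, spec.entry_band)
    weights = {"never": never, "current": current, "former": former}
    entry = initial_state_vector(bundle.use_prevalence, spec.sex, spec.entry_band)

    traces: dict[str, CohortTrace] = {}
    for state, weight in weights.items():
        if weight <= 0.0:
            continue
        v = np.zeros(N_STATES)
        if state == "never":
            v[NEVER] = entry[NEVER]
        elif state == "current":
            v[CURRENT] = entry[CURRENT]
        else:
            v[F1 : FLONG + 1] = entry[F1 : FLONG + 1]
        v = v / weight
        occupancy = np.zeros_like(full.occupancy)
        occupancy[0] = v
        for t in range(len(full.ages) - 1):
            v = v @ full.matrices[t]
            occupancy[t + 1] = v
        traces[state] = CohortTrace(
            spec=CohortSpec(
                country=spec.country,
                sex=spec.sex,
                entry_band=spec.entry_band,
                scenario="status_quo",
                initial_state=state,
            ),
            ages=full.ages,
            occupancy=occupancy,
            shares=full.shares,
        )
    return full, traces, weights
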