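"""Behavioural transition probabilities: schedule, matrices, calibration.

Annual probabilities of initiation (never -> current), successful
quitting (current -> first tunnel year) and relapse (tunnel year t ->
current, declining with time since quitting) drive movement between use
states; death is resolved first within each cycle using status-specific
mortality.

Initiation and quit probabilities are not observed directly: they are
calibrated so that a cohort stepped forward through the model reproduces
the cross-sectional never/current/former prevalence of the next 5-year
age band (synthetic-cohort assumption: cross-sectional age differences
are read as longitudinal change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .inputs import BundleValidationError, LifeTable, RiskSet, UseStatePrevalence
from .risk import effective_multipliers, status_specific_rate
from .states import CURRENT, DEAD, F1, F10, FLONG, N_STATES, NEVER, exposure_shares

logger = logging.getLogger(__name__)

_BRENTQ_KW = dict(xtol=1e-14, rtol=8.9e-16, maxiter=200)


@dataclass(eq=False)
class TransitionSchedule:
    """Per-age initiation/quit probabilities plus the relapse schedule.

    ``initiation[sex][age - age_min]`` is the annual never -> current
    probability; likewise ``quit`` for current -> former year 1.
    ``relapse[t-1]`` is the annual probability of returning to current
    use in tunnel year t (t = 1..10); ``relapse_tail`` applies beyond ten
    years since quitting.
    """

    initiation: dict[str, np.ndarray]
    quit: dict[str, np.ndarray]
    relapse: np.ndarray
    relapse_tail: float = 0.0
    age_min: int = 15

    def __post_init__(self) -> None:
        self.initiation = {s: np.asarray(v, dtype=float) for s, v in self.initiation.items()}
        self.quit = {s: np.asarray(v, dtype=float) for s, v in self.quit.items()}
        self.relapse = np.asarray(self.relapse, dtype=float)

    def _lookup(self, table: dict[str, np.ndarray], sex: str, age: int) -> float:
        arr = table[sex]
        idx = min(max(age - self.age_min, 0), len(arr) - 1)
        if age < self.age_min:
            raise KeyError(f"schedule has no ages below {self.age_min}")
        return float(arr[idx])

    def i(self, sex: str, age: int) -> float:
        """Initiation probability; held at the last value above the grid."""
        return self._lookup(self.initiation, sex, age)

    def c(self, sex: str, age: int) -> float:
        """Quit probability; held at the last value above the grid."""
        return self._lookup(self.quit, sex, age)

    def validate(self) -> None:
        for table, label in ((self.initiation, "initiation"), (self.quit, "quit")):
            for sex, arr in table.items():
                if np.any(arr < 0) or np.any(arr > 1):
                    raise BundleValidationError(
                        f"{label} probabilities for {sex!r} outside [0,1]"
                    )
        if self.relapse.shape != (10,):
            raise BundleValidationError("relapse schedule must cover tunnel years 1..10")
        if np.any(self.relapse < 0) or np.any(self.relapse > 1):
            raise BundleValidationError("relapse probabilities outside [0,1]")
        if np.any(np.diff(self.relapse) > 1e-12):
            raise BundleValidationError("relapse must be non-increasing in time since quitting")
        if not 0.0 <= self.relapse_tail <= self.relapse[-1] + 1e-12:
            raise BundleValidationError("relapse tail must be <= the year-10 relapse")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, table in (("initiation", self.initiation), ("quit", self.quit)):
            for sex in sorted(table):
                for offset, value in enumerate(table[sex]):
                    rows.append(
                        {"kind": kind, "sex": sex, "index": self.age_min + offset, "value": value}
                    )
        for t, value in enumerate(self.relapse, start=1):
            rows.append({"kind": "relapse", "sex": "all", "index": t, "value": value})
        rows.append({"kind": "relapse_tail", "sex": "all", "index": 0, "value": self.relapse_tail})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionSchedule":
        initiation: dict[str, np.ndarray] = {}
        quit: dict[str, np.ndarray] = {}
        age_min = int(df.loc[df["kind"] == "initiation", "index"].min())
        for kind, target in (("initiation", initiation), ("quit", quit)):
            sub = df[df["kind"] == kind]
            for sex, grp in sub.groupby("sex"):
                target[str(sex)] = grp.sort_values("index")["value"].to_numpy()
        rel = df[df["kind"] == "relapse"].sort_values("index")["value"].to_numpy()
        tail = float(df.loc[df["kind"] == "relapse_tail", "value"].iloc[0])
        return cls(initiation=initiation, quit=quit, relapse=rel, relapse_tail=tail, age_min=age_min)

    def equals(self, other: "TransitionSchedule") -> bool:
        return (
            self.age_min == other.age_min
            and self.relapse_tail == other.relapse_tail
            and np.array_equal(self.relapse, other.relapse)
            and set(self.initiation) == set(other.initiation)
            and all(np.array_equal(self.initiation[s], other.initiation[s]) for s in self.initiation)
            and set(self.quit) == set(other.quit)
            and all(np.array_equal(self.quit[s], other.quit[s]) for s in self.quit)
        )

    def relapse_at(self, tunnel_year: int) -> float:
        return float(self.relapse[tunnel_year - 1])


# ---------------------------------------------------------------------------
# transition matrix


def build_transition_matrix(
    initiation: float,
    quit: float,
    relapse: np.ndarray,
    relapse_tail: float,
    class_mortality: np.ndarray,
) -> np.ndarray:
    """Assemble the 14x14 annual transition matrix for one (sex, age).

    Death is resolved first at each state's exposure-class probability;
    behaviour change applies to survivors.  Tunnel states advance by one
    year unless the member relapses; dead is absorbing.  Every row sums
    to 1 by construction.
    """
    q = np.asarray(class_mortality, dtype=float)
    probs = {"initiation": initiation, "quit": quit, "relapse_tail": relapse_tail}
    for t, r in enumerate(np.asarray(relapse, dtype=float), start=1):
        probs[f"relapse[{t}]"] = float(r)
    for cls, value in enumerate(q):
        probs[f"mortality[{cls}]"] = float(value)
    for name, value in probs.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"transition probability {name} = {value} outside [0,1]")

    m = np.zeros((N_STATES, N_STATES))
    m[NEVER, DEAD] = q[0]
    m[NEVER, CURRENT] = (1.0 - q[0]) * initiation
    m[NEVER, NEVER] = (1.0 - q[0]) * (1.0 - initiation)

    m[CURRENT, DEAD] = q[1]
    m[CURRENT, F1] = (1.0 - q[1]) * quit
    m[CURRENT, CURRENT] = (1.0 - q[1]) * (1.0 - quit)

    for t in range(1, 11):
        state = F1 + t - 1
        q_t = q[2] if t <= 5 else q[3]
        r_t = float(relapse[t - 1])
        nxt = state + 1 if t < 10 else FLONG
        m[state, DEAD] = q_t
        m[state, CURRENT] = (1.0 - q_t) * r_t
        m[state, nxt] = (1.0 - q_t) * (1.0 - r_t)

    m[FLONG, DEAD] = q[4]
    m[FLONG, CURRENT] = (1.0 - q[4]) * relapse_tail
    m[FLONG, FLONG] = (1.0 - q[4]) * (1.0 - relapse_tail)

    m[DEAD, DEAD] = 1.0
    return m


def class_mortality(
    life_table: LifeTable,
    risk_set: RiskSet,
    sex: str,
    age: int,
    shares: np.ndarray,
    min_risk_age: int,
) -> np.ndarray:
    """Status-specific annual death probabilities anchored to the life table.

    The share-weighted mean over exposure classes equals the life-table
    probability, so all-cause mortality is conserved whatever the mix.
    """
    mult = effective_multipliers(risk_set, "mortality", age, min_risk_age)
    return status_specific_rate(life_table.prob(sex, age), shares, mult)


def advance(
    v: np.ndarray,
    initiation: float,
    quit: float,
    relapse: np.ndarray,
    relapse_tail: float,
    q_class: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One annual cycle: returns (new occupancy, matrix used)."""
    m = build_transition_matrix(initiation, quit, relapse, relapse_tail, q_class)
    return v @ m, m


# ---------------------------------------------------------------------------
# calibration


def _band_pairs(prevalence: UseStatePrevalence, sex: str):
    bands = prevalence.bands(sex)
    for b, b_next in zip(bands, bands[1:]):
        if b_next[0] != b[0] + 5:
            raise BundleValidationError(
                f"use prevalence bands for {sex!r} are not consecutive: "
                f"{b} followed by {b_next}"
            )
    return list(zip(bands, bands[1:]))


def _expand_bands(
    values: dict[tuple[int, int], float], prevalence: UseStatePrevalence, sex: str, n_ages: int, age_min: int
) -> np.ndarray:
    """Per-band constants -> per-age array, holding the last band's value."""
    arr = np.zeros(n_ages)
    last = 0.0
    for offset in range(n_ages):
        age = age_min + offset
        band = None
        for b in values:
            if b[0] <= age <= b[1]:
                band = b
                break
        if band is not None:
            last = values[band]
        arr[offset] = last
    return arr


def calibrate_initiation(
    prevalence: UseStatePrevalence,
    life_table: LifeTable,
    risk_set: RiskSet,
    sex: str,
    *,
    min_risk_age: int = 35,
    former_split: np.ndarray | None = None,
    horizon_age: int = 89,
) -> np.ndarray:
    """Annual initiation probabilities reproducing the never-user gradient.

    For each pair of consecutive bands, finds the constant annual
    probability that moves the never-user share from the observed value
    at one band to the observed value at the next over five cycles,
    accounting for differential survival of never versus ever users
    (ever-user mortality mixes the current/former classes at their
    observed composition).  Clamped to [0, 1] with a logged warning when
    the observed share increases with age.
    """
    from .engine import population_exposure_shares

    def never_share_after(i: float, band) -> float:
        n, _, f = prevalence.at_band(sex, band)
        never, ever = n, 1.0 - n
        for age in range(band[0], band[0] + 5):
            shares = population_exposure_shares(prevalence, sex, age, former_split)
            qv = class_mortality(life_table, risk_set, sex, age, shares, min_risk_age)
            ever_shares = shares[1:]
            tot = ever_shares.sum()
            q_e = float(ever_shares @ qv[1:]) / tot if tot > 0 else qv[0]
            q_n = qv[0]
            never, ever = (
                never * (1.0 - q_n) * (1.0 - i),
                ever * (1.0 - q_e) + never * (1.0 - q_n) * i,
            )
        return never / (never + ever)

    by_band: dict[tuple[int, int], float] = {}
    for band, band_next in _band_pairs(prevalence, sex):
        target = prevalence.at_band(sex, band_next)[0]
        f = lambda i: never_share_after(i, band) - target  # noqa: E731
        if f(0.0) <= 0.0:
            if f(0.0) < -1e-12:
                logger.warning(
                    "initiation clamped to 0 for %s band %s (never share increases with age)",
                    sex,
                    band,
                )
            by_band[band] = 0.0
        elif f(1.0) >= 0.0:
            logger.warning("initiation clamped to 1 for %s band %s", sex, band)
            by_band[band] = 1.0
        else:
            by_band[band] = float(brentq(f, 0.0, 1.0, **_BRENTQ_KW))
    n_ages = horizon_age - 15
    return _expand_bands(by_band, prevalence, sex, n_ages, 15)


def _project_band(
    v: np.ndarray,
    sex: str,
    band,
    i_value: float,
    c_value: float,
    relapse: np.ndarray,
    relapse_tail: float,
    life_table: LifeTable,
    risk_set: RiskSet,
    min_risk_age: int,
) -> np.ndarray:
    """Step a full state vector across one 5-year band (cohort-shares mortality)."""
    for age in range(band[0], band[0] + 5):
        shares = exposure_shares(v)
        qv = class_mortality(life_table, risk_set, sex, age, shares, min_risk_age)
        v, _ = advance(v, i_value, c_value, relapse, relapse_tail, qv)
    return v


def _alive_shares(v: np.ndarray) -> tuple[float, float, float]:
    alive = v[:DEAD].sum()
    never = v[NEVER] / alive
    current = v[CURRENT] / alive
    former = (v[F1 : F10 + 1].sum() + v[FLONG]) / alive
    return never, current, former


def calibrate_quit(
    prevalence: UseStatePrevalence,
    relapse: np.ndarray,
    life_table: LifeTable,
    risk_set: RiskSet,
    sex: str,
    initiation: np.ndarray,
    *,
    relapse_tail: float = 0.0,
    min_risk_age: int = 35,
    former_split: np.ndarray | None = None,
    horizon_age: int = 89,
) -> np.ndarray:
    """Annual quit probabilities reproducing the former-user gradient.

    Steps the full 14-state vector forward band by band (chained, so the
    tunnel composition evolves consistently) and root-finds, per band,
    the constant annual quit probability that lands the former-user
    share on the next band's observed value given initiation, relapse
    and differential mortality.  Clamped to [0, 1] with a warning when no
    root exists.
    """
    from .engine import initial_state_vector

    bands = prevalence.bands(sex)
    v = initial_state_vector(prevalence, sex, bands[0], former_split)
    by_band: dict[tuple[int, int], float] = {}
    for band, band_next in _band_pairs(prevalence, sex):
        i_value = float(initiation[band[0] - 15])
        target = prevalence.at_band(sex, band_next)[2]

        def former_after(c: float) -> float:
            vv = _project_band(
                v, sex, band, i_value, c, relapse, relapse_tail,
                life_table, risk_set, min_risk_age,
            )
            return _alive_shares(vv)[2]

        f = lambda c: former_after(c) - target  # noqa: E731
        if f(0.0) >= 0.0:
            if f(0.0) > 1e-12:
                logger.warning(
                    "quit probability clamped to 0 for %s band %s (former share "
                    "target below zero-quitting projection)", sex, band,
                )
            c_value = 0.0
        elif f(1.0) <= 0.0:
            logger.warning("quit probability clamped to 1 for %s band %s", sex, band)
            c_value = 1.0
        else:
            c_value = float(brentq(f, 0.0, 1.0, **_BRENTQ_KW))
        by_band[band] = c_value
        v = _project_band(
            v, sex, band, i_value, c_value, relapse, relapse_tail,
            life_table, risk_set, min_risk_age,
        )
    n_ages = horizon_age - 15
    return _expand_bands(by_band, prevalence, sex, n_ages, 15)


def calibrate_schedule(
    bundle,
    *,
    relapse: np.ndarray | None = None,
    relapse_tail: float = 0.0,
    tol: float = 1e-13,
    max_iter: int = 50,
) -> TransitionSchedule:
    """Jointly calibrate initiation and quit schedules for every sex.

    Refines the two one-dimensional calibrations by per-band fixed-point
    iteration on the full state vector, so that the model's projected
    never- and former-user shares both hit the observed values at every
    band boundary (to solver tolerance, where a root exists in [0, 1]).
    """
    from .defaults import default_relapse
    from .engine import initial_state_vector

    if relapse is None:
        relapse = default_relapse()
    cfg = bundle.config
    prevalence = bundle.use_prevalence
    life_table = bundle.life_table
    risk_set = bundle.risk_set
    n_ages = cfg.horizon_age - 15

    initiation: dict[str, np.ndarray] = {}
    quit: dict[str, np.ndarray] = {}
    for sex in cfg.sexes:
        seed_i = calibrate_initiation(
            prevalence, life_table, risk_set, sex,
            min_risk_age=cfg.min_risk_age, horizon_age=cfg.horizon_age,
        )
        bands = prevalence.bands(sex)
        v = initial_state_vector(prevalence, sex, bands[0])
        i_by_band: dict[tuple[int, int], float] = {}
        c_by_band: dict[tuple[int, int], float] = {}
        for band, band_next in _band_pairs(prevalence, sex):
            never_target = prevalence.at_band(sex, band_next)[0]
            former_target = prevalence.at_band(sex, band_next)[2]
            i_b = float(seed_i[band[0] - 15])
            c_b = 0.05

            def project(i_val: float, c_val: float) -> tuple[float, float, float]:
                return _alive_shares(
                    _project_band(
                        v, sex, band, i_val, c_val, relapse, relapse_tail,
                        life_table, risk_set, cfg.min_risk_age,
                    )
                )

            for _ in range(max_iter):
                f_i = lambda x: project(x, c_b)[0] - never_target  # noqa: E731
                if f_i(0.0) <= 0.0:
                    i_b = 0.0
                elif f_i(1.0) >= 0.0:
                    logger.warning("initiation clamped to 1 for %s band %s", sex, band)
                    i_b = 1.0
                else:
                    i_b = float(brentq(f_i, 0.0, 1.0, **_BRENTQ_KW))
                f_c = lambda x: project(i_b, x)[2] - former_target  # noqa: E731
                if f_c(0.0) >= 0.0:
                    if f_c(0.0) > 1e-12:
                        logger.warning(
                            "quit clamped to 0 for %s band %s (former-share target "
                            "%.4f below zero-quitting projection %.4f)",
                            sex, band, former_target, f_c(0.0) + former_target,
                        )
                    c_b = 0.0
                elif f_c(1.0) <= 0.0:
                    logger.warning("quit clamped to 1 for %s band %s", sex, band)
                    c_b = 1.0
                else:
                    c_b = float(brentq(f_c, 0.0, 1.0, **_BRENTQ_KW))
                n_err = abs(project(i_b, c_b)[0] - never_target)
                former_err = abs(project(i_b, c_b)[2] - former_target)
                clamped_i = i_b in (0.0, 1.0)
                clamped_c = c_b in (0.0, 1.0)
                if (n_err < tol or clamped_i) and (former_err < tol or clamped_c):
                    break
            if n_err > 1e-9 and not clamped_i:
                logger.warning(
                    "never-share residual %.3g for %s band %s after calibration",
                    n_err, sex, band,
                )
            i_by_band[band] = i_b
            c_by_band[band] = c_b
            v = _project_band(
                v, sex, band, i_b, c_b, relapse, relapse_tail,
                life_table, risk_set, cfg.min_risk_age,
            )
        initiation[sex] = _expand_bands(i_by_band, prevalence, sex, n_ages, 15)
        quit[sex] = _expand_bands(c_by_band, prevalence, sex, n_ages, 15)

    schedule = TransitionSchedule(
        initiation=initiation, quit=quit, relapse=relapse, relapse_tail=relapse_tail
    )
    schedule.validate()
    return schedule


def projected_prevalence(bundle, schedule: TransitionSchedule, sex: str) -> pd.DataFrame:
    """Model-projected banded never/current/former shares versus observed.

    Runs the cohort engine from the youngest band and reads the alive
    shares at each band boundary.  Used as the calibration
    self-consistency report.
    """
    from .engine import CohortSpec, run_cohort

    bands = bundle.use_prevalence.bands(sex)
    spec = CohortSpec(country=bundle.country, sex=sex, entry_band=bands[0], scenario="status_quo")
    trace = run_cohort(bundle, spec, schedule)
    rows = []
    for band in bands:
        idx = band[0] - bands[0][0]
        never, current, former = _alive_shares(trace.occupancy[idx])
        obs = bundle.use_prevalence.at_band(sex, band)
        rows.append(
            {
                "sex": sex,
                "age_band": f"{band[0]}-{band[1]}",
                "never_projected": never,
                "never_observed": obs[0],
                "current_projected": current,
                "current_observed": obs[1],
                "former_projected": former,
                "former_observed": obs[2],
            }
        )
    df = pd.DataFrame(rows)
    df["max_abs_error"] = np.max(
        np.abs(
            df[["never_projected", "current_projected", "former_projected"]].to_numpy()
            - df[["never_observed", "current_observed", "former_observed"]].to_numpy()
        ),
        axis=1,
    )
    return df
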