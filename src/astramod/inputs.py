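"""Input data structures, validation, and on-disk bundle format.

A :class:`CountryInputBundle` collects everything the model needs for one
country: the run configuration, a life table, tobacco-use prevalence by
age band and sex, prevalence of the four modelled diseases, relative
effects, disability weights, unit costs, cohort population counts and the
sampling distributions used in probabilistic sensitivity analysis.

Bundles round-trip losslessly through a directory of UTF-8 CSV files
(long format, one header row) plus a YAML config, so published input
tables can be substituted for the synthetic fixtures verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .bands import (
    Band,
    DEFAULT_ENTRY_BANDS,
    DISABILITY_BANDS,
    DISEASE_PREV_BANDS,
    band_for_age,
    format_band,
    parse_band,
)
from .risk import DISEASES, OUTCOMES

SEXES = ("male", "female")

#: Risk-set strata, in declining-exposure order (former_10p is pinned at 1).
RISK_STRATA = ("current", "former_0_4", "former_5_10", "former_10p")


class BundleValidationError(ValueError):
    """An input table violates one of the model's invariants."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings.

    Costs and outcomes are discounted at ``discount_rate`` per annum;
    cohorts are followed to ``horizon_age`` in annual cycles; use carries
    no excess risk below ``min_risk_age``.
    """

    discount_rate: float = 0.03
    horizon_age: int = 89
    cycle_length: int = 1
    min_risk_age: int = 35
    psa_draws: int = 5000
    rng_seed: int = 0
    entry_bands: tuple[Band, ...] = DEFAULT_ENTRY_BANDS
    sexes: tuple[str, ...] = SEXES
    no_st_mortality: str = "never"  # {"never", "population"}
    gamma_mode: str = "cv10"  # {"cv10", "table1"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise BundleValidationError("discount_rate must be in [0, 1)")
        if self.cycle_length != 1:
            raise BundleValidationError("only annual cycles are supported")
        max_entry = max(b[0] for b in self.entry_bands)
        if self.horizon_age < max_entry:
            raise BundleValidationError("horizon_age must be >= the oldest entry age")
        if not 15 <= self.min_risk_age <= self.horizon_age:
            raise BundleValidationError("min_risk_age must lie in [15, horizon_age]")
        if self.psa_draws < 1:
            raise BundleValidationError("psa_draws must be >= 1")
        if self.no_st_mortality not in ("never", "population"):
            raise BundleValidationError("no_st_mortality must be 'never' or 'population'")
        if self.gamma_mode not in ("cv10", "table1"):
            raise BundleValidationError("gamma_mode must be 'cv10' or 'table1'")
        object.__setattr__(self, "entry_bands", tuple(tuple(b) for b in self.entry_bands))
        object.__setattr__(self, "sexes", tuple(self.sexes))

    def to_dict(self) -> dict:
        return {
            "discount_rate": self.discount_rate,
            "horizon_age": self.horizon_age,
            "cycle_length": self.cycle_length,
            "min_risk_age": self.min_risk_age,
            "psa_draws": self.psa_draws,
            "rng_seed": self.rng_seed,
            "entry_bands": [format_band(b) for b in self.entry_bands],
            "sexes": list(self.sexes),
            "no_st_mortality": self.no_st_mortality,
            "gamma_mode": self.gamma_mode,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelConfig":
        data = dict(data)
        if "entry_bands" in data:
            data["entry_bands"] = tuple(parse_band(b) for b in data["entry_bands"])
        if "sexes" in data:
            data["sexes"] = tuple(data["sexes"])
        return cls(**data)


# ---------------------------------------------------------------------------
# epidemiological tables


@dataclass(eq=False)
class LifeTable:
    """Annual all-cause death probabilities by sex and single year of age."""

    q: dict[str, np.ndarray]
    age_min: int = 15

    def __post_init__(self) -> None:
        self.q = {sex: np.asarray(v, dtype=float) for sex, v in self.q.items()}

    @property
    def age_max(self) -> int:
        return self.age_min + len(next(iter(self.q.values()))) - 1

    def prob(self, sex: str, age: int) -> float:
        arr = self.q[sex]
        idx = age - self.age_min
        if not 0 <= idx < len(arr):
            raise KeyError(f"life table has no entry for ({sex}, age {age})")
        return float(arr[idx])

    def validate(self, sexes=SEXES, horizon_age: int = 89) -> None:
        for sex in sexes:
            if sex not in self.q:
                raise BundleValidationError(f"life table missing sex {sex!r}")
            arr = self.q[sex]
            if self.age_min > 15 or self.age_min + len(arr) - 1 < horizon_age:
                raise BundleValidationError(
                    f"life table for {sex!r} must cover ages 15..{horizon_age}"
                )
            if np.any(arr < 0) or np.any(arr > 1):
                bad = int(np.argmax((arr < 0) | (arr > 1)))
                raise BundleValidationError(
                    f"life table q out of [0,1] at ({sex}, age {self.age_min + bad})"
                )

    def equals(self, other: "LifeTable") -> bool:
        return (
            self.age_min == other.age_min
            and set(self.q) == set(other.q)
            and all(np.array_equal(self.q[s], other.q[s]) for s in self.q)
        )


@dataclass(eq=False)
class UseStatePrevalence:
    """Never/current/former tobacco-use shares by sex and 5-year band."""

    table: dict[tuple[str, Band], tuple[float, float, float]]

    def bands(self, sex: str) -> list[Band]:
        return sorted(b for (s, b) in self.table if s == sex)

    def at_band(self, sex: str, band: Band) -> tuple[float, float, float]:
        key = (sex, tuple(band))
        if key not in self.table:
            raise BundleValidationError(
                f"use prevalence missing band {format_band(band)} for {sex!r}"
            )
        return self.table[key]

    def at_age(self, sex: str, age: int) -> tuple[float, float, float]:
        """Constant interpolation within bands; clamped beyond the grid."""
        bands = tuple(self.bands(sex))
        return self.at_band(sex, band_for_age(age, bands))

    def validate(self, sexes=SEXES, entry_bands=DEFAULT_ENTRY_BANDS) -> None:
        for sex in sexes:
            have = set(self.bands(sex))
            for band in entry_bands:
                if tuple(band) not in have:
                    raise BundleValidationError(
                        f"use prevalence missing band {format_band(band)} for {sex!r}"
                    )
        for (sex, band), triple in self.table.items():
            if len(triple) != 3:
                raise BundleValidationError(
                    f"use prevalence at ({sex}, {format_band(band)}) is not a triple"
                )
            if any(not 0.0 <= v <= 1.0 for v in triple):
                raise BundleValidationError(
                    f"use prevalence component outside [0,1] at ({sex}, {format_band(band)})"
                )
            if abs(sum(triple) - 1.0) > 1e-9:
                raise BundleValidationError(
                    f"use prevalence at ({sex}, {format_band(band)}) sums to "
                    f"{sum(triple):.10f}, not 1"
                )

    def equals(self, other: "UseStatePrevalence") -> bool:
        return set(self.table) == set(other.table) and all(
            self.table[k] == other.table[k] for k in self.table
        )


@dataclass(eq=False)
class DiseasePrevalenceTable:
    """Population prevalence of each modelled disease by sex and band."""

    table: dict[tuple[str, str, Band], float]

    def at_age(self, disease: str, sex: str, age: int) -> float:
        bands = tuple(sorted(b for (d, s, b) in self.table if d == disease and s == sex))
        if not bands:
            raise BundleValidationError(
                f"disease prevalence missing for ({disease}, {sex})"
            )
        return self.table[(disease, sex, band_for_age(age, bands))]

    def validate(self, sexes=SEXES) -> None:
        present = {d for (d, _, _) in self.table}
        for disease in DISEASES:
            if disease not in present:
                raise BundleValidationError(f"disease prevalence missing {disease!r}")
        for (disease, sex, band), value in self.table.items():
            if disease not in DISEASES:
                raise BundleValidationError(f"unknown disease {disease!r}")
            if not 0.0 <= value < 1.0:
                raise BundleValidationError(
                    f"disease prevalence outside [0,1) at "
                    f"({disease}, {sex}, {format_band(band)})"
                )

    def equals(self, other: "DiseasePrevalenceTable") -> bool:
        return self.table == other.table


@dataclass(eq=False)
class RiskSet:
    """Relative effects versus never users, per outcome and exposure stratum.

    Strata are (current, former 0-4y, former 5-10y, former 10+y); the last
    is pinned at exactly 1 — risk returns to the never-user level ten
    years after quitting.
    """

    table: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.table = {k: np.asarray(v, dtype=float) for k, v in self.table.items()}

    def multipliers(self, outcome: str) -> np.ndarray:
        if outcome not in self.table:
            raise KeyError(f"risk set has no outcome {outcome!r}")
        return self.table[outcome]

    def validate(self) -> None:
        for outcome in OUTCOMES:
            if outcome not in self.table:
                raise BundleValidationError(f"risk set missing outcome {outcome!r}")
            m = self.table[outcome]
            if m.shape != (4,):
                raise BundleValidationError(
                    f"risk set for {outcome!r} must have 4 strata {RISK_STRATA}"
                )
            if np.any(m <= 0):
                raise BundleValidationError(f"risk multipliers must be > 0 ({outcome})")
            if m[3] != 1.0:
                raise BundleValidationError(
                    f"former_10p multiplier must equal 1 exactly ({outcome})"
                )
            if np.any(np.diff(m) > 1e-12):
                raise BundleValidationError(
                    f"risk multipliers must be non-increasing across strata ({outcome})"
                )

    def equals(self, other: "RiskSet") -> bool:
        return set(self.table) == set(other.table) and all(
            np.array_equal(self.table[k], other.table[k]) for k in self.table
        )


@dataclass(eq=False)
class DisabilityWeightTable:
    """Average disability weight per prevalent case, by disease/sex/age band."""

    table: dict[tuple[str, str, Band], float]

    def weight(self, disease: str, sex: str, age: int) -> float:
        band = band_for_age(age, DISABILITY_BANDS)
        key = (disease, sex, band)
        if key not in self.table:
            raise BundleValidationError(
                f"disability weight missing for ({disease}, {sex}, {format_band(band)})"
            )
        return self.table[key]

    def validate(self, sexes=SEXES) -> None:
        for disease in DISEASES:
            for sex in sexes:
                for band in DISABILITY_BANDS:
                    if (disease, sex, band) not in self.table:
                        raise BundleValidationError(
                            f"disability weight missing for "
                            f"({disease}, {sex}, {format_band(band)})"
                        )
        for key, w in self.table.items():
            if not 0.0 < w < 1.0:
                raise BundleValidationError(
                    f"disability weight must be in (0,1) at {key}"
                )

    def equals(self, other: "DisabilityWeightTable") -> bool:
        return self.table == other.table


@dataclass(frozen=True)
class CostTable:
    """Annual treatment costs (USD) per prevalent case.

    One cancer cost applies to all three cancers.  Stroke distinguishes
    first-year (incident) from subsequent-year (prevalent) cases; by
    default 10% of prevalent strokes are within their first year.
    """

    annual_cancer_cost: float
    incident_stroke_cost: float
    prevalent_stroke_cost: float
    incident_stroke_fraction: float = 0.10

    def validate(self) -> None:
        if min(self.annual_cancer_cost, self.incident_stroke_cost, self.prevalent_stroke_cost) < 0:
            raise BundleValidationError("costs must be non-negative")
        if self.prevalent_stroke_cost > self.incident_stroke_cost:
            raise BundleValidationError(
                "prevalent stroke cost must not exceed incident stroke cost"
            )
        if not 0.0 <= self.incident_stroke_fraction <= 1.0:
            raise BundleValidationError("incident_stroke_fraction must be in [0,1]")

    def annual_stroke_cost(self) -> float:
        f = self.incident_stroke_fraction
        return f * self.incident_stroke_cost + (1.0 - f) * self.prevalent_stroke_cost

    def cost_for(self, disease: str) -> float:
        if disease == "stroke":
            return self.annual_stroke_cost()
        return self.annual_cancer_cost

    def equals(self, other: "CostTable") -> bool:
        return self == other


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling specification for one uncertain parameter.

    ``kind`` is one of lognormal (params: mean-of-log, se-of-log), beta
    (alpha, beta), gamma (shape, scale) or fixed (no params).  The point
    estimate drives the deterministic run; the distribution drives PSA.
    """

    kind: str
    params: tuple[float, ...]
    point_estimate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind == "lognormal":
            mu, se = self.params
            if se <= 0:
                raise BundleValidationError("lognormal se must be > 0")
            if not math.isclose(math.exp(mu), self.point_estimate, rel_tol=0.02):
                raise BundleValidationError(
                    f"lognormal exp(mu)={math.exp(mu):.4f} differs from point "
                    f"estimate {self.point_estimate} by more than 2%"
                )
        elif self.kind == "beta":
            a, b = self.params
            if a <= 0 or b <= 0:
                raise BundleValidationError("beta parameters must be > 0")
            if abs(a / (a + b) - self.point_estimate) > 1e-6:
                raise BundleValidationError(
                    f"beta mean {a / (a + b):.8f} does not match point estimate "
                    f"{self.point_estimate}"
                )
        elif self.kind == "gamma":
            shape, scale = self.params
            if shape <= 0 or scale <= 0:
                raise BundleValidationError("gamma parameters must be > 0")
        elif self.kind == "fixed":
            if self.params not in ((), (self.point_estimate,)):
                object.__setattr__(self, "params", ())
        else:
            raise BundleValidationError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "lognormal":
            mu, se = self.params
            return math.exp(mu + se**2 / 2.0)
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        if self.kind == "gamma":
            shape, scale = self.params
            return shape * scale
        return self.point_estimate


@dataclass(eq=False)
class CohortPopulation:
    """Population count entering each (sex, 5-year band) cohort."""

    table: dict[tuple[str, Band], float]

    def count(self, sex: str, band: Band) -> float:
        key = (sex, tuple(band))
        if key not in self.table:
            raise BundleValidationError(
                f"population missing for ({sex}, {format_band(band)})"
            )
        return self.table[key]

    def validate(self, sexes=SEXES, entry_bands=DEFAULT_ENTRY_BANDS) -> None:
        for sex in sexes:
            for band in entry_bands:
                self.count(sex, band)
        for key, n in self.table.items():
            if n < 0:
                raise BundleValidationError(f"population must be >= 0 at {key}")

    def equals(self, other: "CohortPopulation") -> bool:
        return self.table == other.table


# ---------------------------------------------------------------------------
# the bundle


@dataclass(eq=False)
class CountryInputBundle:
    """All model inputs for one country, validated as a unit."""

    country: str
    config: ModelConfig
    life_table: LifeTable
    use_prevalence: UseStatePrevalence
    disease_prevalence: DiseasePrevalenceTable
    risk_set: RiskSet
    disability_weights: DisabilityWeightTable
    costs: CostTable
    population: CohortPopulation
    distributions: dict[str, ParameterDistribution] = field(default_factory=dict)
    schedule: Optional["object"] = None  # TransitionSchedule, set by calibration

    def validate(self) -> "CountryInputBundle":
        cfg = self.config
        self.life_table.validate(cfg.sexes, cfg.horizon_age)
        self.use_prevalence.validate(cfg.sexes, cfg.entry_bands)
        self.disease_prevalence.validate(cfg.sexes)
        self.risk_set.validate()
        self.disability_weights.validate(cfg.sexes)
        self.costs.validate()
        self.population.validate(cfg.sexes, cfg.entry_bands)
        return self

    def with_(self, **kwargs) -> "CountryInputBundle":
        """Shallow copy with selected fields replaced."""
        return replace(self, **kwargs)

    def equals(self, other: "CountryInputBundle") -> bool:
        if self.country != other.country or self.config != other.config:
            return False
        if not (
            self.life_table.equals(other.life_table)
            and self.use_prevalence.equals(other.use_prevalence)
            and self.disease_prevalence.equals(other.disease_prevalence)
            and self.risk_set.equals(other.risk_set)
            and self.disability_weights.equals(other.disability_weights)
            and self.costs == other.costs
            and self.population.equals(other.population)
            and self.distributions == other.distributions
        ):
            return False
        if (self.schedule is None) != (other.schedule is None):
            return False
        if self.schedule is not None and not self.schedule.equals(other.schedule):
            return False
        return True


# ---------------------------------------------------------------------------
# on-disk format

_FILES = {
    "config": "config.yaml",
    "life_table": "life_table.csv",
    "use_prevalence": "use_prevalence.csv",
    "disease_prevalence": "disease_prevalence.csv",
    "risks": "risks.csv",
    "disability_weights": "disability_weights.csv",
    "costs": "costs.csv",
    "population": "population.csv",
    "distributions": "distributions.csv",
    "schedule": "schedule.csv",
}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    """CSV reader preserving float values exactly (lossless round-trip)."""
    return pd.read_csv(path, float_precision="round_trip")


def write_bundle(bundle: CountryInputBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as a directory of CSV tables plus a YAML config.

    Deterministic: identical bundles produce byte-identical files.
    Returns the mapping of table name to file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}

    cfg = {"country": bundle.country, **bundle.config.to_dict()}
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")

    lt = bundle.life_table
    rows = [
        {"sex": sex, "age": lt.age_min + i, "q": q}
        for sex in sorted(lt.q)
        for i, q in enumerate(lt.q[sex])
    ]
    _write_csv(pd.DataFrame(rows), paths["life_table"])

    rows = [
        {"sex": sex, "age_band": format_band(band), "status": status, "value": value}
        for (sex, band), triple in sorted(bundle.use_prevalence.table.items())
        for status, value in zip(("never", "current", "former"), triple)
    ]
    _write_csv(pd.DataFrame(rows), paths["use_prevalence"])

    rows = [
        {"disease": d, "sex": s, "age_band": format_band(b), "value": v}
        for (d, s, b), v in sorted(bundle.disease_prevalence.table.items())
    ]
    _write_csv(pd.DataFrame(rows), paths["disease_prevalence"])

    rows = [
        {"outcome": outcome, "stratum": stratum, "value": value}
        for outcome, mult in sorted(bundle.risk_set.table.items())
        for stratum, value in zip(RISK_STRATA, mult)
    ]
    _write_csv(pd.DataFrame(rows), paths["risks"])

    rows = [
        {"disease": d, "sex": s, "age_band": format_band(b), "value": v}
        for (d, s, b), v in sorted(bundle.disability_weights.table.items())
    ]
    _write_csv(pd.DataFrame(rows), paths["disability_weights"])

    c = bundle.costs
    rows = [
        {"item": "annual_cancer_cost", "value": c.annual_cancer_cost},
        {"item": "incident_stroke_cost", "value": c.incident_stroke_cost},
        {"item": "prevalent_stroke_cost", "value": c.prevalent_stroke_cost},
        {"item": "incident_stroke_fraction", "value": c.incident_stroke_fraction},
    ]
    _write_csv(pd.DataFrame(rows), paths["costs"])

    rows = [
        {"sex": s, "age_band": format_band(b), "value": v}
        for (s, b), v in sorted(bundle.population.table.items())
    ]
    _write_csv(pd.DataFrame(rows), paths["population"])

    rows = [
        {
            "name": name,
            "kind": dist.kind,
            "param1": dist.params[0] if dist.params else "",
            "param2": dist.params[1] if len(dist.params) > 1 else "",
            "point_estimate": dist.point_estimate,
        }
        for name, dist in sorted(bundle.distributions.items())
    ]
    _write_csv(pd.DataFrame(rows), paths["distributions"])

    if bundle.schedule is not None:
        _write_csv(bundle.schedule.to_frame(), paths["schedule"])
    else:
        paths.pop("schedule")

    return paths


def load_bundle(directory: str | Path) -> CountryInputBundle:
    """Load and validate a bundle written by :func:`write_bundle`."""
    from .transitions import TransitionSchedule

    directory = Path(directory)
    missing = [
        name
        for name, fname in _FILES.items()
        if name != "schedule" and not (directory / fname).exists()
    ]
    if missing:
        raise BundleValidationError(f"bundle at {directory} missing tables: {missing}")

    cfg_data = yaml.safe_load((directory / _FILES["config"]).read_text(encoding="utf-8"))
    country = cfg_data.pop("country")
    config = ModelConfig.from_dict(cfg_data)

    df = read_csv(directory / _FILES["life_table"])
    q: dict[str, np.ndarray] = {}
    age_min = int(df["age"].min())
    for sex, grp in df.groupby("sex"):
        grp = grp.sort_values("age")
        q[str(sex)] = grp["q"].to_numpy()
    life_table = LifeTable(q=q, age_min=age_min)

    df = read_csv(directory / _FILES["use_prevalence"])
    use_table: dict[tuple[str, Band], tuple[float, float, float]] = {}
    for (sex, band_s), grp in df.groupby(["sex", "age_band"]):
        vals = dict(zip(grp["status"], grp["value"]))
        use_table[(str(sex), parse_band(str(band_s)))] = (
            float(vals["never"]),
            float(vals["current"]),
            float(vals["former"]),
        )
    use_prevalence = UseStatePrevalence(use_table)

    df = read_csv(directory / _FILES["disease_prevalence"])
    disease_prevalence = DiseasePrevalenceTable(
        {
            (str(r.disease), str(r.sex), parse_band(str(r.age_band))): float(r.value)
            for r in df.itertuples()
        }
    )

    df = read_csv(directory / _FILES["risks"])
    risk_table: dict[str, np.ndarray] = {}
    for outcome, grp in df.groupby("outcome"):
        vals = dict(zip(grp["stratum"], grp["value"]))
        risk_table[str(outcome)] = np.array([vals[s] for s in RISK_STRATA])
    risk_set = RiskSet(risk_table)

    df = read_csv(directory / _FILES["disability_weights"])
    disability_weights = DisabilityWeightTable(
        {
            (str(r.disease), str(r.sex), parse_band(str(r.age_band))): float(r.value)
            for r in df.itertuples()
        }
    )

    df = read_csv(directory / _FILES["costs"]).set_index("item")["value"]
    costs = CostTable(
        annual_cancer_cost=float(df["annual_cancer_cost"]),
        incident_stroke_cost=float(df["incident_stroke_cost"]),
        prevalent_stroke_cost=float(df["prevalent_stroke_cost"]),
        incident_stroke_fraction=float(df["incident_stroke_fraction"]),
    )

    df = read_csv(directory / _FILES["population"])
    population = CohortPopulation(
        {(str(r.sex), parse_band(str(r.age_band))): float(r.value) for r in df.itertuples()}
    )

    df = read_csv(directory / _FILES["distributions"])
    distributions: dict[str, ParameterDistribution] = {}
    for r in df.itertuples():
        params: tuple[float, ...] = ()
        if str(r.kind) != "fixed":
            params = (float(r.param1), float(r.param2))
        distributions[str(r.name)] = ParameterDistribution(
            kind=str(r.kind), params=params, point_estimate=float(r.point_estimate)
        )

    schedule = None
    if (directory / _FILES["schedule"]).exists():
        schedule = TransitionSchedule.from_frame(
            read_csv(directory / _FILES["schedule"])
        )

    bundle = CountryInputBundle(
        country=country,
        config=config,
        life_table=life_table,
        use_prevalence=use_prevalence,
        disease_prevalence=disease_prevalence,
        risk_set=risk_set,
        disability_weights=disability_weights,
        costs=costs,
        population=population,
        distributions=distributions,
        schedule=schedule,
    )
    return bundle.validate()
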