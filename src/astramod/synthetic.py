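"""Synthetic country input bundles.

Generates statistically plausible stand-ins for the model's data sources
so the whole pipeline is testable without any external download: GATS-style
never/current/former use prevalence by 5-year band and sex (current use
low in adolescence, peaking in middle age; men using more than women),
Gompertz-increasing all-cause mortality, GBD-style disease prevalence
rising with age, UN-style population counts declining with age, and the
packaged relative-effect/disability-weight/cost defaults.

Deterministic given the seed: the seed jitters the parameters of smooth
age curves (never per-band noise), so monotonicity properties needed by
the calibration — never-user share declining and former-user share rising
with age — hold for every seed.
"""

from __future__ import annotations

import numpy as np

from .bands import DEFAULT_ENTRY_BANDS, DISEASE_PREV_BANDS
from .defaults import (
    default_costs,
    default_disability_weights,
    default_distributions,
    default_risk_set,
    null_risk_set,
)
from .inputs import (
    CohortPopulation,
    CountryInputBundle,
    DiseasePrevalenceTable,
    LifeTable,
    ModelConfig,
    ParameterDistribution,
    UseStatePrevalence,
)

_KNOBS = {
    "st_prevalence_scale",  # scales current+former use; 0 => nobody ever uses
    "null_risks",  # all relative effects fixed at 1
    "population_scale",
    "costs_country",  # {"india_pakistan", "bangladesh"}
    "discount_rate",
    "horizon_age",
    "min_risk_age",
    "psa_draws",
    "gamma_mode",
    "no_st_mortality",
    "country",
}

#: Use-prevalence curve parameters per sex:
#: never(a) = base + amp * exp(-(a-15)/decay);
#: former(a) = fmax * (1 - exp(-(a-15)/frate)).
_USE_CURVES = {
    "male": {"base": 0.52, "amp": 0.43, "decay": 12.0, "fmax": 0.30, "frate": 30.0},
    "female": {"base": 0.75, "amp": 0.22, "decay": 14.0, "fmax": 0.12, "frate": 30.0},
}

#: Gompertz mortality: q(a) = min(0.7, q15 * exp(slope * (a - 15))).
_MORTALITY = {"male": {"q15": 0.0016, "slope": 0.082}, "female": {"q15": 0.0012, "slope": 0.082}}

#: Logistic disease prevalence: cap / (1 + exp(-(a - mid)/width)).
_DISEASES_CURVES = {
    "oral_cancer": {"cap": 0.0040, "mid": 62.0, "width": 11.0},
    "pharyngeal_cancer": {"cap": 0.0022, "mid": 64.0, "width": 11.0},
    "esophageal_cancer": {"cap": 0.0030, "mid": 66.0, "width": 10.0},
    "stroke": {"cap": 0.060, "mid": 72.0, "width": 9.0},
}
_DISEASE_SEX_FACTOR = {"male": 1.15, "female": 0.85}

#: Entering population: base * exp(-0.045 * (band_low - 15)).
_POPULATION_BASE = {"male": 6.0e6, "female": 5.7e6}


def _jitter(rng: np.random.Generator, value: float, rel: float = 0.10) -> float:
    return value * (1.0 + rel * rng.uniform(-1.0, 1.0))


def make_synthetic_bundle(seed: int, knobs: dict | None = None) -> CountryInputBundle:
    """Build a valid, fully populated synthetic country bundle.

    ``knobs`` may override selected generator/config settings; unknown
    keys or out-of-domain values raise immediately.
    """
    knobs = dict(knobs or {})
    unknown = set(knobs) - _KNOBS
    if unknown:
        raise ValueError(f"unknown synthetic-bundle knobs: {sorted(unknown)}")
    st_scale = float(knobs.get("st_prevalence_scale", 1.0))
    if not 0.0 <= st_scale <= 1.0:
        raise ValueError("st_prevalence_scale must be in [0, 1]")
    pop_scale = float(knobs.get("population_scale", 1.0))
    if pop_scale < 0:
        raise ValueError("population_scale must be >= 0")
    costs_country = knobs.get("costs_country", "india_pakistan")

    config = ModelConfig(
        discount_rate=float(knobs.get("discount_rate", 0.03)),
        horizon_age=int(knobs.get("horizon_age", 89)),
        min_risk_age=int(knobs.get("min_risk_age", 35)),
        psa_draws=int(knobs.get("psa_draws", 5000)),
        rng_seed=int(seed),
        gamma_mode=str(knobs.get("gamma_mode", "cv10")),
        no_st_mortality=str(knobs.get("no_st_mortality", "never")),
    )
    rng = np.random.default_rng(seed)

    # life table (ages 15..horizon)
    ages = np.arange(15, config.horizon_age + 1)
    q: dict[str, np.ndarray] = {}
    for sex in config.sexes:
        p = _MORTALITY[sex]
        q15 = _jitter(rng, p["q15"], 0.10)
        slope = _jitter(rng, p["slope"], 0.05)
        q[sex] = np.minimum(0.7, q15 * np.exp(slope * (ages - 15)))
    life_table = LifeTable(q=q, age_min=15)

    # tobacco-use prevalence by entry band (evaluated at band lower bound)
    use_table = {}
    for sex in config.sexes:
        p = _USE_CURVES[sex]
        amp = _jitter(rng, p["amp"], 0.08)
        base = min(_jitter(rng, p["base"], 0.05), 1.0 - amp)
        decay = _jitter(rng, p["decay"], 0.10)
        fmax = _jitter(rng, p["fmax"], 0.10)
        frate = _jitter(rng, p["frate"], 0.10)
        for band in DEFAULT_ENTRY_BANDS:
            a = band[0]
            never_curve = base + amp * np.exp(-(a - 15) / decay)
            former_curve = fmax * (1.0 - np.exp(-(a - 15) / frate))
            current = st_scale * (1.0 - never_curve - former_curve)
            former = st_scale * former_curve
            never = 1.0 - current - former
            use_table[(sex, band)] = (never, current, former)
    use_prevalence = UseStatePrevalence(use_table)

    # disease prevalence by 5-year band to 85-89 (band midpoints)
    disease_table = {}
    for disease, p in _DISEASES_CURVES.items():
        cap = _jitter(rng, p["cap"], 0.10)
        mid = _jitter(rng, p["mid"], 0.03)
        width = _jitter(rng, p["width"], 0.05)
        for sex in config.sexes:
            factor = _DISEASE_SEX_FACTOR[sex]
            for band in DISEASE_PREV_BANDS:
                a = band[0] + 2.0
                disease_table[(disease, sex, band)] = float(
                    factor * cap / (1.0 + np.exp(-(a - mid) / width))
                )
    disease_prevalence = DiseasePrevalenceTable(disease_table)

    # population counts entering each cohort
    pop_table = {}
    for sex in config.sexes:
        base = _POPULATION_BASE[sex] * pop_scale
        for band in DEFAULT_ENTRY_BANDS:
            count = base * np.exp(-0.045 * (band[0] - 15)) * (1.0 + 0.05 * rng.uniform(-1, 1))
            pop_table[(sex, band)] = float(round(count))
    population = CohortPopulation(pop_table)

    if knobs.get("null_risks", False):
        risk_set = null_risk_set()
        distributions = default_distributions(costs_country, config.gamma_mode)
        for name in list(distributions):
            if name.startswith("rr_"):
                distributions[name] = ParameterDistribution(
                    kind="fixed", params=(), point_estimate=1.0
                )
    else:
        risk_set = default_risk_set()
        distributions = default_distributions(costs_country, config.gamma_mode)

    bundle = CountryInputBundle(
        country=str(knobs.get("country", "synthland")),
        config=config,
        life_table=life_table,
        use_prevalence=use_prevalence,
        disease_prevalence=disease_prevalence,
        risk_set=risk_set,
        disability_weights=default_disability_weights(config.sexes),
        costs=default_costs(costs_country),
        population=population,
        distributions=distributions,
    )
    return bundle.validate()
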