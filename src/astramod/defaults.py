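"""Packaged default parameter values.

Relative effects, disability weights, stroke incident fraction and unit
costs come from the published model input table: lognormal relative
effects (log-mean, log-SE) for mortality and the four diseases by
time-since-quit stratum, Beta(alpha, beta) disability weights with
alpha + beta = 50, a Beta(5, 45) incident-stroke fraction, and country
cost sets (India and Pakistan share one set; Bangladesh has its own).

Cost uncertainty: the printed gamma parameterizations are inconsistent
with the USD point estimates (they appear to be on an unconverted
original scale), so the default PSA parameterization is Gamma with
shape 100 and scale = point/100 — mean equal to the point estimate and a
10% coefficient of variation.  The verbatim printed parameters remain
loadable via ``gamma_mode="table1"``.
"""

from __future__ import annotations

import numpy as np

from .inputs import CostTable, DisabilityWeightTable, ParameterDistribution, RiskSet
from .risk import DISEASES

#: (point estimate, log-mean, log-SE) per outcome and stratum
#: (current, former 0-4y, former 5-10y); former 10+ is pinned at 1.
RELATIVE_EFFECTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "mortality": ((1.25, 0.22, 0.07), (1.09, 0.08, 0.10), (1.02, 0.02, 0.10)),
    "esophageal_cancer": ((3.17, 1.15, 0.07), (1.77, 0.56, 0.10), (1.21, 0.18, 0.10)),
    "oral_cancer": ((5.55, 1.71, 0.05), (2.61, 0.95, 0.10), (1.45, 0.36, 0.10)),
    "pharyngeal_cancer": ((2.69, 0.99, 0.08), (1.56, 0.44, 0.10), (1.16, 0.14, 0.10)),
    "stroke": ((1.37, 0.31, 0.12), (1.13, 0.12, 0.10), (1.04, 0.03, 0.10)),
}

#: Disability weights per prevalent case by broad age band
#: (15-49, 50-69, 70+); Beta parameters are (50*w, 50*(1-w)).
DISABILITY_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "oral_cancer": (0.164, 0.172, 0.196),
    "esophageal_cancer": (0.143, 0.165, 0.191),
    "pharyngeal_cancer": (0.207, 0.236, 0.370),
    "stroke": (0.210, 0.236, 0.375),
}

_DW_BANDS = ((15, 49), (50, 69), (70, 200))
_DW_BAND_KEYS = ("15_49", "50_69", "70_plus")

#: Proportion of prevalent strokes that are within their first year.
INCIDENT_STROKE_FRACTION = 0.10
INCIDENT_STROKE_BETA = (5.0, 45.0)

#: Annual USD costs per prevalent case by country group.
COSTS: dict[str, dict[str, float]] = {
    "india_pakistan": {
        "annual_cancer_cost": 2164.0,
        "incident_stroke_cost": 821.0,
        "prevalent_stroke_cost": 82.0,
    },
    "bangladesh": {
        "annual_cancer_cost": 791.0,
        "incident_stroke_cost": 601.0,
        "prevalent_stroke_cost": 60.0,
    },
}

#: Verbatim printed gamma parameters (second entry of "Gamma (100, x)").
#: Not USD-consistent; used only under gamma_mode="table1".
TABLE1_GAMMA_SCALE: dict[str, dict[str, float]] = {
    "india_pakistan": {
        "annual_cancer_cost": 1523.68,
        "incident_stroke_cost": 578.04,
        "prevalent_stroke_cost": 57.80,
    },
    "bangladesh": {
        "annual_cancer_cost": 667.90,
        "incident_stroke_cost": 507.77,
        "prevalent_stroke_cost": 50.78,
    },
}

#: Default relapse schedule: annual probability of returning to current
#: use in tunnel year t, geometrically declining, zero after ten years.
RELAPSE_FIRST_YEAR = 0.15
RELAPSE_RATIO = 0.65


def default_relapse() -> np.ndarray:
    return RELAPSE_FIRST_YEAR * RELAPSE_RATIO ** np.arange(10)


def default_risk_set() -> RiskSet:
    return RiskSet(
        {
            outcome: np.array([row[0][0], row[1][0], row[2][0], 1.0])
            for outcome, row in RELATIVE_EFFECTS.items()
        }
    )


def default_disability_weights(sexes=("male", "female")) -> DisabilityWeightTable:
    table = {}
    for disease, weights in DISABILITY_WEIGHTS.items():
        for sex in sexes:
            for band, w in zip(_DW_BANDS, weights):
                table[(disease, sex, band)] = w
    return DisabilityWeightTable(table)


def default_costs(country_costs: str = "india_pakistan") -> CostTable:
    if country_costs not in COSTS:
        raise KeyError(f"unknown cost country group {country_costs!r}")
    return CostTable(incident_stroke_fraction=INCIDENT_STROKE_FRACTION, **COSTS[country_costs])


def default_distributions(
    country_costs: str = "india_pakistan", gamma_mode: str = "cv10"
) -> dict[str, ParameterDistribution]:
    """The full PSA distribution set keyed by parameter name."""
    dists: dict[str, ParameterDistribution] = {}
    strata = ("current", "former_0_4", "former_5_10")
    for outcome, rows in RELATIVE_EFFECTS.items():
        for stratum, (point, mu, se) in zip(strata, rows):
            dists[f"rr_{outcome}_{stratum}"] = ParameterDistribution(
                kind="lognormal", params=(mu, se), point_estimate=point
            )
    for disease, weights in DISABILITY_WEIGHTS.items():
        for key, w in zip(_DW_BAND_KEYS, weights):
            dists[f"dw_{disease}_{key}"] = ParameterDistribution(
                kind="beta", params=(50.0 * w, 50.0 * (1.0 - w)), point_estimate=w
            )
    dists["incident_stroke_fraction"] = ParameterDistribution(
        kind="beta", params=INCIDENT_STROKE_BETA, point_estimate=INCIDENT_STROKE_FRACTION
    )
    for item, point in COSTS[country_costs].items():
        if gamma_mode == "table1":
            params = (100.0, TABLE1_GAMMA_SCALE[country_costs][item])
        else:
            params = (100.0, point / 100.0)
        dists[f"cost_{item}"] = ParameterDistribution(
            kind="gamma", params=params, point_estimate=point
        )
    return dists


def null_risk_set() -> RiskSet:
    """All multipliers 1: tobacco use carries no excess risk anywhere."""
    return RiskSet({outcome: np.ones(4) for outcome in ("mortality", *DISEASES)})
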