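"""Probabilistic sensitivity analysis.

Every uncertain parameter (relative effects, disability weights, unit
costs, the incident-stroke fraction) is sampled from its assigned
distribution, the deterministic pipeline is re-run per draw with the
behaviour schedule held at its calibrated values, and 95% credible
intervals are taken as the empirical 2.5th/97.5th percentiles of the
draws.  Parameters are sampled independently; structural constraints
(former-10+ effect pinned at 1, effects non-increasing with time since
quitting and at least 1, prevalent stroke no dearer than incident) are
re-enforced by resampling the offending parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import Band
from .burden import burden_for_cohort
from .inputs import (
    CostTable,
    CountryInputBundle,
    DisabilityWeightTable,
    ParameterDistribution,
    RiskSet,
)
from .risk import DISEASES, OUTCOMES
from .transitions import TransitionSchedule

logger = logging.getLogger(__name__)

_DW_KEYS = {(15, 49): "15_49", (50, 69): "50_69", (70, 200): "70_plus"}
_METRICS = ("ly_gained", "yld_averted", "dalys_averted", "cost_averted")
_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class PSAResult:
    """Point estimate plus the Monte Carlo draws for one output."""

    point: float
    draws: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def ci_low(self) -> float:
        return float(np.percentile(self.draws, 2.5))

    @property
    def ci_high(self) -> float:
        return float(np.percentile(self.draws, 97.5))


def sample_parameter(
    dist: ParameterDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw from one parameter's distribution."""
    if dist.kind == "lognormal":
        mu, se = dist.params
        return np.exp(rng.normal(mu, se, size=size))
    if dist.kind == "beta":
        a, b = dist.params
        return rng.beta(a, b, size=size)
    if dist.kind == "gamma":
        shape, scale = dist.params
        return rng.gamma(shape, scale, size=size)
    if dist.kind == "fixed":
        if size is None:
            return dist.point_estimate
        return np.full(size, dist.point_estimate)
    raise ValueError(f"unknown distribution kind {dist.kind!r}")


def _sample_effect_triple(
    dists: dict[str, ParameterDistribution], outcome: str, rng: np.random.Generator
) -> np.ndarray:
    """Sample (current, former 0-4, former 5-10, 1) with monotonicity.

    Resamples the triple until the effects are non-increasing with time
    since quitting and do not dip below the never-user reference.
    """
    names = [f"rr_{outcome}_{s}" for s in ("current", "former_0_4", "former_5_10")]
    for attempt in range(_MAX_RESAMPLE):
        draw = [
            sample_parameter(dists[name], rng) if name in dists else 1.0
            for name in names
        ]
        if draw[0] >= draw[1] >= draw[2] >= 1.0:
            if attempt > 0:
                logger.debug("resampled %s effects %d time(s)", outcome, attempt)
            return np.array([*draw, 1.0])
    raise RuntimeError(f"could not draw monotone effects for {outcome}")


def draw_parameter_set(
    bundle: CountryInputBundle, rng: np.random.Generator
) -> CountryInputBundle:
    """One PSA draw: a bundle copy with sampled parameter values."""
    dists = bundle.distributions

    risk_table = {
        outcome: _sample_effect_triple(dists, outcome, rng) for outcome in OUTCOMES
    }
    risk_set = RiskSet(risk_table)

    dw_table = dict(bundle.disability_weights.table)
    for disease in DISEASES:
        for band, key in _DW_KEYS.items():
            name = f"dw_{disease}_{key}"
            if name not in dists:
                continue
            w = float(sample_parameter(dists[name], rng))
            for sex in bundle.config.sexes:
                dw_table[(disease, sex, band)] = w
    weights = DisabilityWeightTable(dw_table)

    def cost_draw(name: str, fallback: float) -> float:
        if name in dists:
            return float(sample_parameter(dists[name], rng))
        return fallback

    cancer = cost_draw("cost_annual_cancer_cost", bundle.costs.annual_cancer_cost)
    incident = cost_draw("cost_incident_stroke_cost", bundle.costs.incident_stroke_cost)
    for attempt in range(_MAX_RESAMPLE):
        prevalent = cost_draw(
            "cost_prevalent_stroke_cost", bundle.costs.prevalent_stroke_cost
        )
        if prevalent <= incident:
            break
    else:
        raise RuntimeError("could not draw prevalent stroke cost <= incident cost")
    fraction = (
        float(sample_parameter(dists["incident_stroke_fraction"], rng))
        if "incident_stroke_fraction" in dists
        else bundle.costs.incident_stroke_fraction
    )
    costs = CostTable(
        annual_cancer_cost=cancer,
        incident_stroke_cost=incident,
        prevalent_stroke_cost=prevalent,
        incident_stroke_fraction=fraction,
    )
    return bundle.with_(risk_set=risk_set, disability_weights=weights, costs=costs)


def run_psa(
    bundle: CountryInputBundle,
    schedule: TransitionSchedule,
    cohorts: list[tuple[str, Band]],
    n_draws: int,
    seed: int,
) -> dict[tuple[str, Band], dict[str, PSAResult]]:
    """Monte Carlo uncertainty analysis over the given cohorts.

    Returns, per (sex, entry band) and per output metric, the point
    estimate from the unperturbed bundle together with the draws.
    Reproducible given the seed; the behaviour schedule is held fixed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    cohorts = [(sex, tuple(band)) for sex, band in cohorts]

    points = {
        key: burden_for_cohort(bundle, key[0], key[1], schedule) for key in cohorts
    }
    draws = {key: {m: np.zeros(n_draws) for m in _METRICS} for key in cohorts}
    for d in range(n_draws):
        try:
            perturbed = draw_parameter_set(bundle, rng)
            for key in cohorts:
                result = burden_for_cohort(perturbed, key[0], key[1], schedule)
                for m in _METRICS:
                    draws[key][m][d] = getattr(result, m)
        except Exception:
            logger.error("PSA draw %d failed (seed %d)", d, seed)
            raise

    return {
        key: {
            m: PSAResult(
                point=getattr(points[key], m), draws=draws[key][m], seed=seed
            )
            for m in _METRICS
        }
        for key in cohorts
    }
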