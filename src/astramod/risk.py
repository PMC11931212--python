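"""Apportioning population rates across tobacco-use exposure classes.

Population-level annual mortality probabilities (life table) and disease
prevalences (GBD-style extracts) describe the whole population.  The model
needs them split by use status.  Given relative effects ``m_k`` versus
never users and exposure-class shares ``s_k`` summing to one, the
never-user rate consistent with the population rate ``p`` is

    r_never = p / sum_k s_k * m_k,        r_k = m_k * r_never,

so the share-weighted mean of the class-specific rates reproduces ``p``
exactly (conservation).  The same algebra yields the population
attributable fraction

    PAF = sum_k s_k (m_k - 1) / (1 + sum_k s_k (m_k - 1)) = 1 - r_never / p.

Use is assumed to have no effect below a minimum age (default 35), where
every multiplier collapses to one.
"""

from __future__ import annotations

import logging

import numpy as np

from .states import CLASS_NAMES, N_CLASSES

logger = logging.getLogger(__name__)

_SHARE_TOL = 1e-9

OUTCOMES = (
    "mortality",
    "oral_cancer",
    "pharyngeal_cancer",
    "esophageal_cancer",
    "stroke",
)
DISEASES = OUTCOMES[1:]


def _check_shares(shares: np.ndarray) -> np.ndarray:
    shares = np.asarray(shares, dtype=float)
    if shares.shape != (N_CLASSES,):
        raise ValueError(
            f"exposure shares must have length {N_CLASSES} ({CLASS_NAMES})"
        )
    if np.any(shares < -1e-15):
        raise ValueError("exposure shares must be non-negative")
    if abs(shares.sum() - 1.0) > _SHARE_TOL:
        raise ValueError(f"exposure shares sum to {shares.sum():.12f}, not 1")
    return shares


def effective_multipliers(risk_set, outcome: str, age: int, min_risk_age: int) -> np.ndarray:
    """Relative effects by exposure class at a given age.

    Below ``min_risk_age`` tobacco use is assumed to carry no excess risk,
    so every class multiplier is one.  Otherwise the risk-set values for
    (current, former 0-4y, former 5-10y, former 10+y) apply, prefixed with
    the never-user reference of 1.
    """
    if outcome not in OUTCOMES:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if age < min_risk_age:
        return np.ones(N_CLASSES)
    return np.concatenate(([1.0], risk_set.multipliers(outcome)))


def status_specific_rate(
    pop_rate: float,
    exposure_shares: np.ndarray,
    multipliers: np.ndarray,
) -> np.ndarray:
    """Split a population rate into exposure-class-specific rates.

    Returns one rate per class; the share-weighted mean of the result
    equals ``pop_rate``.  Rates are capped at 1 (with a logged warning)
    so that extreme sensitivity-analysis draws cannot produce invalid
    probabilities.
    """
    if not 0.0 <= pop_rate < 1.0:
        raise ValueError(f"population rate must be in [0, 1), got {pop_rate}")
    shares = _check_shares(exposure_shares)
    mult = np.asarray(multipliers, dtype=float)
    if mult.shape != (N_CLASSES,):
        raise ValueError(f"multipliers must have length {N_CLASSES}")
    if np.any(mult <= 0):
        raise ValueError("multipliers must be positive")
    r_never = pop_rate / float(shares @ mult)
    rates = mult * r_never
    if np.any(rates > 1.0):
        logger.warning(
            "status-specific rate capped at 1 (pop_rate=%g, max uncapped=%g)",
            pop_rate,
            rates.max(),
        )
        rates = np.minimum(rates, 1.0)
    return rates


def attributable_fraction(exposure_shares: np.ndarray, multipliers: np.ndarray) -> float:
    """Population attributable fraction for one outcome.

    Equals ``1 - r_never / pop_rate`` from :func:`status_specific_rate`;
    lies in [0, 1) whenever all multipliers are at least 1.
    """
    shares = _check_shares(exposure_shares)
    mult = np.asarray(multipliers, dtype=float)
    if np.any(mult <= 0):
        raise ValueError("multipliers must be positive")
    excess = float(shares @ (mult - 1.0))
    return excess / (1.0 + excess)
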