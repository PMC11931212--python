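"""The model's state space.

A cohort member is always in exactly one of 14 mutually exclusive states:
never user, current user, one of ten former-user tunnel states (one per
year since quitting, entered in sequence), the long-term former state
(10+ years since quitting) and dead.  Disease is not a state: disease
prevalence is overlaid on the living states each cycle.

For risk purposes the living states collapse onto five exposure classes:
never, current, former 0-4 years, former 5-10 years and former 10+ years
(tunnel years 1-5, 6-10 and the long-term state respectively).
"""

from __future__ import annotations

import numpy as np

STATE_NAMES: tuple[str, ...] = (
    "never",
    "current",
    *(f"former_{t}" for t in range(1, 11)),
    "former_long",
    "dead",
)

N_STATES = len(STATE_NAMES)
NEVER, CURRENT = 0, 1
F1 = 2  # first tunnel state; former_t sits at index F1 + t - 1
F10 = 11
FLONG = 12
DEAD = 13

#: Exposure classes used for relative risks.
CLASS_NAMES: tuple[str, ...] = (
    "never",
    "current",
    "former_0_4",
    "former_5_10",
    "former_10p",
)
N_CLASSES = 5

#: Exposure class of each living state (dead excluded).
CLASS_OF_STATE = np.array(
    [0, 1, 2, 2, 2, 2, 2, 3, 3, 3, 3, 3, 4], dtype=np.intp
)


def exposure_shares(occupancy: np.ndarray) -> np.ndarray:
    """Exposure-class shares among the alive portion of a state vector.

    Returns a length-5 vector summing to 1.  Raises if nobody is alive.
    """
    alive = occupancy[:DEAD]
    total = float(alive.sum())
    if total <= 0.0:
        raise ValueError("exposure shares undefined: no occupancy in living states")
    shares = np.zeros(N_CLASSES)
    np.add.at(shares, CLASS_OF_STATE, alive)
    return shares / total


def state_mortality(class_mortality: np.ndarray) -> np.ndarray:
    """Expand per-exposure-class death probabilities to the living states."""
    return np.asarray(class_mortality, dtype=float)[CLASS_OF_STATE]
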