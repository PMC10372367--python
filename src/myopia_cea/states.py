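"""Health states of the myopia progression model.

The model classifies a child's refractive status by cycloplegic spherical
equivalent (SE, diopters) into four mutually exclusive states.  The SE
intervals partition the real line:

* ``NON_MYOPIA``  SE > -0.5 D
* ``LOW``         -3.0 D <  SE <= -0.5 D
* ``MODERATE``    -6.0 D <  SE <= -3.0 D
* ``HIGH``        SE <= -6.0 D

States are ordered by increasing severity; the cohort engine forbids
transitions toward less myopic states (myopia does not regress).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import ValidationError

MIN_AGE = 6
MAX_AGE = 18
N_CYCLES = MAX_AGE - MIN_AGE + 1  # 13 age points, 12 transitions


class HealthState(IntEnum):
    NON_MYOPIA = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


#: Half-open SE interval (lower, upper] in diopters for each state.
SE_RANGES: dict[HealthState, tuple[float, float]] = {
    HealthState.NON_MYOPIA: (-0.5, math.inf),
    HealthState.LOW: (-3.0, -0.5),
    HealthState.MODERATE: (-6.0, -3.0),
    HealthState.HIGH: (-math.inf, -6.0),
}

STATE_LABELS = ("non", "low", "moderate", "high")


def state_for_se(se: float) -> HealthState:
    """Classify a spherical-equivalent value (diopters) into a health state."""
    if se > -0.5:
        return HealthState.NON_MYOPIA
    if se > -3.0:
        return HealthState.LOW
    if se > -6.0:
        return HealthState.MODERATE
    return HealthState.HIGH


SUM_TOL = 1e-9


@dataclass(frozen=True)
class HealthStateDistribution:
    """Occupancy fractions over the four states at one integer age.

    ``occupancy`` is ordered (non, low, moderate, high); entries are
    dimensionless fractions that must sum to one within 1e-9.
    """

    occupancy: np.ndarray
    age: int

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.shape != (4,):
            raise ValidationError(f"occupancy must have 4 entries, got shape {occ.shape}")
        if np.any(occ < -SUM_TOL) or np.any(occ > 1 + SUM_TOL):
            raise ValidationError(f"occupancy entries must lie in [0, 1]: {occ}")
        if abs(occ.sum() - 1.0) > SUM_TOL:
            raise ValidationError(f"occupancy must sum to 1 (got {occ.sum():.12f})")
        if not float(self.age).is_integer() or not MIN_AGE <= self.age <= MAX_AGE:
            raise ValidationError(f"age must be an integer in [{MIN_AGE}, {MAX_AGE}], got {self.age}")
        object.__setattr__(self, "age", int(self.age))

    @property
    def total_myopia(self) -> float:
        """Fraction in any myopic state (1 - non-myopia occupancy)."""
        return float(1.0 - self.occupancy[HealthState.NON_MYOPIA])

    def fraction(self, state: HealthState) -> float:
        return float(self.occupancy[state])

    @classmethod
    def from_myopia_prevalences(cls, low: float, moderate: float, high: float, age: int
                                ) -> "HealthStateDistribution":
        """Build a distribution from the three myopic-state prevalences (fractions)."""
        non = 1.0 - (low + moderate + high)
        return cls(np.array([non, low, moderate, high], dtype=float), age)
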