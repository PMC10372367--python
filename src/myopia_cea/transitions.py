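"""Annual state-to-state transition matrices.

The natural history of the model is a progression chain
non -> low -> moderate -> high with no regression: all entries below the
diagonal are zero, and HIGH is absorbing.  One matrix applies per year of
age (the transition taken while ageing from ``age`` to ``age + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .states import MAX_AGE, MIN_AGE, SUM_TOL, STATE_LABELS

ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 matrix of annual transition probabilities at one age."""

    age: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", mat)
        if mat.shape != (4, 4):
            raise ValidationError(f"transition matrix must be 4x4, got {mat.shape}")
        if not MIN_AGE <= self.age < MAX_AGE:
            raise ValidationError(
                f"transition age must be in [{MIN_AGE}, {MAX_AGE - 1}], got {self.age}")
        for i, row in enumerate(mat):
            if np.any(row < -SUM_TOL) or np.any(row > 1 + SUM_TOL):
                raise ValidationError(
                    f"row {i} ({STATE_LABELS[i]}) at age {self.age} has entries outside [0, 1]: {row}")
            if abs(row.sum() - 1.0) > ROW_TOL:
                raise ValidationError(
                    f"row {i} ({STATE_LABELS[i]}) at age {self.age} sums to "
                    f"{row.sum():.12f}, expected 1")
        # irreversibility: no probability mass toward less myopic states
        lower = np.tril(mat, k=-1)
        if np.any(lower > SUM_TOL):
            i, j = np.argwhere(lower > SUM_TOL)[0]
            raise ValidationError(
                f"backward transition {STATE_LABELS[i]} -> {STATE_LABELS[j]} at age "
                f"{self.age} is forbidden (myopia does not regress)")


def progression_matrix(age: int, onset: float, low_to_moderate: float,
                       moderate_to_high: float) -> TransitionMatrix:
    """Build the chain matrix from the three forward annual probabilities.

    ``onset`` is non->low; skips over a severity level within one year are
    not modelled.  HIGH is absorbing.
    """
    for name, p in (("onset", onset), ("low_to_moderate", low_to_moderate),
                    ("moderate_to_high", moderate_to_high)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} at age {age} must be in [0, 1], got {p}")
    mat = np.array([
        [1.0 - onset, onset, 0.0, 0.0],
        [0.0, 1.0 - low_to_moderate, low_to_moderate, 0.0],
        [0.0, 0.0, 1.0 - moderate_to_high, moderate_to_high],
        [0.0, 0.0, 0.0, 1.0],
    ])
    return TransitionMatrix(age=age, probabilities=mat)


def identity_matrix(age: int) -> TransitionMatrix:
    return TransitionMatrix(age=age, probabilities=np.eye(4))
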