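"""Strategy and setting definitions.

Three management strategies are modelled, all built on school-based vision
tests with a non-cycloplegic instrument (imperfect sensitivity/specificity):

* ``school_screening`` — vision tests plus referral of positives to hospital
  examination and treatment; no health education.
* ``traditional`` — screening cascade plus conventional health education
  (posters, brochures, activities) promoting outdoor time.
* ``digital`` — screening cascade plus digital health education (WeChat/SMS),
  with higher education exposure and therefore higher behavioural reach.

Two effect channels modify the natural-history transition probabilities:

* outdoor activity (education-delivered) lowers myopia onset; its reach is
  ``education_exposure * outdoor_compliance`` and does not require a
  positive screen — education targets all students;
* optical/clinical treatment (cascade-delivered) slows progression between
  myopic states; its reach is
  ``coverage * sensitivity * referral_compliance * treatment_compliance``.

Each modifiable probability p becomes ``p * (1 - reach * (1 - multiplier))``,
a population-average mixture of treated (probability scaled by the
multiplier) and untreated children.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ValidationError
from .states import HealthStateDistribution
from .transitions import TransitionMatrix

STRATEGY_NAMES = ("school_screening", "traditional", "digital")


def _check_fraction(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class ScreeningCascade:
    """Per-cycle screening and follow-up cascade for one setting."""

    coverage: float            # fraction of students vision-tested per year
    sensitivity: float         # non-cycloplegic test sensitivity
    specificity: float         # non-cycloplegic test specificity
    referral_compliance: float  # fraction of positives attending hospital exam
    spectacle_compliance: float  # fraction of confirmed myopes treated
    outdoor_compliance: float   # fraction adhering to outdoor-activity advice

    def __post_init__(self) -> None:
        for f in ("coverage", "sensitivity", "specificity", "referral_compliance",
                  "spectacle_compliance", "outdoor_compliance"):
            _check_fraction(f, getattr(self, f))


@dataclass(frozen=True)
class InterventionEffect:
    """Multiplicative effect of one intervention on transition probabilities.

    Multipliers lie in (0, 1]: interventions never worsen progression.
    ``onset_rate_multiplier`` scales non->myopia onset,
    ``progression_rate_multiplier`` scales within-myopia progression.
    """

    applies_to: str
    onset_rate_multiplier: float = 1.0
    progression_rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for f in ("onset_rate_multiplier", "progression_rate_multiplier"):
            v = getattr(self, f)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{f} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class StrategyDefinition:
    """One management strategy resolved for a specific setting."""

    name: str
    cascade: ScreeningCascade
    education_channel: str = "none"      # none | traditional | digital
    education_exposure: float = 0.0      # fraction of students reached by education
    outdoor_effect: InterventionEffect = field(
        default_factory=lambda: InterventionEffect("outdoor"))
    treatment_effect: InterventionEffect = field(
        default_factory=lambda: InterventionEffect("spectacles"))

    def __post_init__(self) -> None:
        if self.education_channel not in ("none", "traditional", "digital"):
            raise ValidationError(f"unknown education channel {self.education_channel!r}")
        _check_fraction("education_exposure", self.education_exposure)

    @property
    def onset_reach(self) -> float:
        """Fraction of the cohort actually exposed to the outdoor-activity effect."""
        r = self.education_exposure * self.cascade.outdoor_compliance
        return _check_fraction("onset reach", r)

    @property
    def treatment_reach(self) -> float:
        """Fraction of myopes receiving treatment through the screening cascade."""
        c = self.cascade
        r = c.coverage * c.sensitivity * c.referral_compliance * c.spectacle_compliance
        return _check_fraction("treatment reach", r)

    def onset_factor(self) -> float:
        """Population-average multiplier applied to the onset probability."""
        return 1.0 - self.onset_reach * (1.0 - self.outdoor_effect.onset_rate_multiplier)

    def progression_factor(self) -> float:
        """Population-average multiplier applied to within-myopia progression."""
        return 1.0 - self.treatment_reach * (
            1.0 - self.treatment_effect.progression_rate_multiplier)

    def with_perfect(self, field_name: str) -> "StrategyDefinition":
        """Return a variant with one compliance field raised to 100%."""
        cascade_fields = {"coverage", "referral_compliance", "spectacle_compliance",
                          "outdoor_compliance"}
        if field_name in cascade_fields:
            return replace(self, cascade=replace(self.cascade, **{field_name: 1.0}))
        if field_name == "education_exposure":
            return replace(self, education_exposure=1.0)
        raise ValidationError(f"unknown compliance field {field_name!r}")


@dataclass(frozen=True)
class SettingContext:
    """A rural or urban population context."""

    name: str
    baseline_distribution: HealthStateDistribution  # at age 6
    gdp_per_capita: float                           # 2021 USD
    cohort_size: int = 100_000

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise ValidationError("gdp_per_capita must be positive")
        if self.cohort_size < 0:
            raise ValidationError("cohort_size must be non-negative")
        if self.baseline_distribution.age != 6:
            raise ValidationError("baseline distribution must be at age 6")


def apply_strategy(matrix: TransitionMatrix, strategy: StrategyDefinition,
                   setting: SettingContext | None = None) -> TransitionMatrix:
    """Apply a strategy's effect channels to a natural-history matrix.

    Off-diagonal forward probabilities are scaled by the population-average
    effect factors; each diagonal entry absorbs the difference so rows stay
    stochastic.  ``setting`` is accepted for interface symmetry (strategies
    are already resolved per setting) and is not otherwise used.
    """
    mat = matrix.probabilities.copy()
    f_on = strategy.onset_factor()
    f_prog = strategy.progression_factor()
    # onset row: all non -> myopic transitions
    mat[0, 1:] *= f_on
    mat[0, 0] = 1.0 - mat[0, 1:].sum()
    # progression rows: low and moderate
    for i in (1, 2):
        mat[i, i + 1:] *= f_prog
        mat[i, i] = 1.0 - mat[i, i + 1:].sum() - mat[i, :i].sum()
    return TransitionMatrix(age=matrix.age, probabilities=mat)
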