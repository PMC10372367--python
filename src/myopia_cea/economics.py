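"""Cost, QALY and DALY accrual, discounting and threshold construction.

Outcomes accrue at each of the 13 annual age points (6..18) and are
discounted to age 6 at a configurable annual rate (default 5%, matching the
cost-adjustment rate used for price updating).  Costs are carried in 2021
USD from a societal perspective: screening and education programme costs,
hospital examination costs for referred screen-positives (true and false),
treatment costs for confirmed myopes, and the associated out-of-hospital
direct costs and family time loss folded into the per-event cost lines.

QALYs use per-state annual utility weights; DALYs use per-state annual
disability weights in a prevalence-based years-lived-with-disability form.
There is no mortality in the model, hence no years-of-life-lost term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .states import N_CYCLES
from .strategies import StrategyDefinition

DEFAULT_EXCHANGE_RATE = 6.45   # CNY per USD, 2021 average
DEFAULT_COST_ADJUSTMENT = 0.05
DEFAULT_DISCOUNT_RATE = 0.05


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-state annual utility and disability weights.

    Utilities must be non-increasing in severity, disability weights
    non-decreasing (worse vision is worth fewer QALYs and more DALYs).
    """

    utility: np.ndarray            # (4,) in state order non, low, moderate, high
    disability_weight: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        u = np.asarray(self.utility, dtype=float)
        d = np.asarray(self.disability_weight, dtype=float)
        object.__setattr__(self, "utility", u)
        object.__setattr__(self, "disability_weight", d)
        for name, arr in (("utility", u), ("disability_weight", d)):
            if arr.shape != (4,):
                raise ConfigurationError(f"{name} must provide a weight for all 4 states")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} weights must lie in [0, 1]: {arr}")
        if np.any(np.diff(u) > 1e-12):
            raise ValidationError(f"utilities must be non-increasing in severity: {u}")
        if np.any(np.diff(d) < -1e-12):
            raise ValidationError(f"disability weights must be non-decreasing in severity: {d}")


@dataclass(frozen=True)
class CostSchedule:
    """Per-event and per-student annual cost lines for one setting (2021 USD).

    Event costs bundle the direct in-hospital fee with the associated
    out-of-hospital direct costs (transport, food, accommodation) and the
    indirect family work-time loss for that visit.
    """

    screening_per_test: float = 0.0       # per student tested per year
    education_traditional: float = 0.0    # per student per year
    education_digital: float = 0.0        # per student per year
    hospital_examination: float = 0.0     # per referred child per visit
    treatment_annual: float = 0.0         # per treated myope per year
    outdoor_program: float = 0.0          # per participating student per year
    capital_share: float = 0.0            # labelled share of programme costs; aggregated identically

    def __post_init__(self) -> None:
        for f in ("screening_per_test", "education_traditional", "education_digital",
                  "hospital_examination", "treatment_annual", "outdoor_program"):
            if getattr(self, f) < 0:
                raise ValidationError(f"cost line {f} must be non-negative")


@dataclass(frozen=True)
class EconomyContext:
    exchange_rate: float = DEFAULT_EXCHANGE_RATE     # CNY per USD
    cost_adjustment_rate: float = DEFAULT_COST_ADJUSTMENT
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    national_gdp_per_capita: float = 12_551.0
    urbanization_rate: float = 0.65
    urban_rural_income_ratio: float = 2.5
    half_cycle_correction: bool = False  # no correction applied by default

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ValidationError("exchange_rate must be positive")
        for f in ("cost_adjustment_rate", "discount_rate"):
            if not 0.0 <= getattr(self, f) < 1.0:
                raise ValidationError(f"{f} must be in [0, 1)")


def convert_currency(amount_cny: float, exchange_rate: float = DEFAULT_EXCHANGE_RATE) -> float:
    """Convert Chinese yuan to US dollars at the 2021 average rate."""
    if amount_cny < 0:
        raise ValidationError("amount must be non-negative")
    return amount_cny / exchange_rate


def inflate_cost(cost: float, from_year: int, to_year: int,
                 rate: float = DEFAULT_COST_ADJUSTMENT) -> float:
    """Bring a historical cost forward by compound annual adjustment."""
    if to_year < from_year:
        raise ValidationError("to_year must not precede from_year (no deflation)")
    return cost * (1.0 + rate) ** (to_year - from_year)


def compute_thresholds(gdp_per_capita: float) -> tuple[float, float]:
    """WHO willingness-to-pay benchmarks: (1x GDP, 3x GDP) per QALY/DALY."""
    if gdp_per_capita <= 0:
        raise ValidationError("gdp_per_capita must be positive")
    return gdp_per_capita, 3.0 * gdp_per_capita


def discount_factors(rate: float, n_cycles: int = N_CYCLES) -> np.ndarray:
    """Discount factor for each age point, (1+r)^-(age-6)."""
    return (1.0 + rate) ** (-np.arange(n_cycles, dtype=float))


def cycle_event_quantities(occupancy: np.ndarray, strategy: StrategyDefinition) -> dict[str, float]:
    """Expected per-person event counts at one age point.

    Returns the utilization quantities that multiply the cost lines:
    screening tests, education exposures, hospital examinations (true
    positives referred plus false positives referred), treated myopes, and
    outdoor participants.
    """
    c = strategy.cascade
    myopic = float(occupancy[1:].sum())
    non = float(occupancy[0])
    referred = (myopic * c.coverage * c.sensitivity
                + non * c.coverage * (1.0 - c.specificity)) * c.referral_compliance
    treated = myopic * c.coverage * c.sensitivity * c.referral_compliance * c.spectacle_compliance
    return {
        "screening_per_test": c.coverage,
        "education_traditional": 1.0 if strategy.education_channel == "traditional" else 0.0,
        "education_digital": 1.0 if strategy.education_channel == "digital" else 0.0,
        "hospital_examination": referred,
        "treatment_annual": treated,
        "outdoor_program": strategy.education_exposure * c.outdoor_compliance,
    }


def cycle_cost(occupancy: np.ndarray, strategy: StrategyDefinition,
               costs: CostSchedule) -> float:
    """Expected undiscounted cost per person at one age point (USD)."""
    q = cycle_event_quantities(occupancy, strategy)
    return sum(q[k] * getattr(costs, k) for k in q)


@dataclass(frozen=True)
class OutcomeTotals:
    cost: float
    qaly: float
    daly: float


def accrue_outcomes(occupancies: np.ndarray, strategy: StrategyDefinition,
                    payoffs: PayoffSchedule, costs: CostSchedule,
                    economy: EconomyContext) -> tuple[np.ndarray, np.ndarray, np.ndarray, OutcomeTotals]:
    """Discounted per-cycle cost/QALY/DALY arrays and their totals (per person).

    ``occupancies`` is the (13, 4) occupancy series of a cohort trace.
    QALY_k = v^k * sum_s occ_s * utility_s, DALY analogously with disability
    weights, cost_k = v^k * expected event costs, with v = 1/(1+discount_rate).
    """
    occ = np.asarray(occupancies, dtype=float)
    if occ.ndim != 2 or occ.shape[1] != 4:
        raise ConfigurationError(f"occupancy series must be (n, 4), got {occ.shape}")
    disc = discount_factors(economy.discount_rate, occ.shape[0])
    qaly = disc * (occ @ payoffs.utility)
    daly = disc * (occ @ payoffs.disability_weight)
    cost = disc * np.array([cycle_cost(o, strategy, costs) for o in occ])
    totals = OutcomeTotals(cost=float(cost.sum()), qaly=float(qaly.sum()), daly=float(daly.sum()))
    return cost, qaly, daly, totals
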