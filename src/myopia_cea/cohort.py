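"""Age-structured Markov cohort engine.

A closed cohort of 6-year-olds is advanced annually to age 18 (13 age
points, 12 transitions).  Each year the natural-history matrix for that age
is modified by the active strategy's effect channels, the occupancy vector
is pushed through the matrix, and discounted costs, QALYs and DALYs accrue
at every age point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import accrue_outcomes, OutcomeTotals
from .errors import TerminalCycleError, ValidationError
from .params import ParameterSet
from .states import MAX_AGE, MIN_AGE, N_CYCLES, HealthStateDistribution
from .strategies import SettingContext, StrategyDefinition, apply_strategy
from .transitions import TransitionMatrix

TRACE_COLUMNS = ("age", "p_non", "p_low", "p_mod", "p_high", "cost", "qaly", "daly",
                 "cum_cost", "cum_qaly", "cum_daly")


def advance_cohort(dist: HealthStateDistribution,
                   matrix: TransitionMatrix) -> HealthStateDistribution:
    """Push the occupancy vector through one annual transition."""
    if dist.age >= MAX_AGE:
        raise TerminalCycleError(f"cohort is already at terminal age {MAX_AGE}")
    if matrix.age != dist.age:
        raise ValidationError(
            f"matrix age {matrix.age} does not match cohort age {dist.age}")
    occupancy = dist.occupancy @ matrix.probabilities
    return HealthStateDistribution(occupancy=occupancy, age=dist.age + 1)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of one setting x strategy cohort run (per person)."""

    setting: str
    strategy: str
    ages: np.ndarray          # (13,)
    occupancy: np.ndarray     # (13, 4)
    cost: np.ndarray          # (13,) discounted USD per person
    qaly: np.ndarray          # (13,) discounted
    daly: np.ndarray          # (13,) discounted
    totals: OutcomeTotals
    discount_rate: float
    label: str = ""           # provenance label propagated from the parameter set

    def __post_init__(self) -> None:
        if len(self.ages) != N_CYCLES:
            raise ValidationError(f"a trace must have {N_CYCLES} age points")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "age": self.ages,
            "p_non": self.occupancy[:, 0],
            "p_low": self.occupancy[:, 1],
            "p_mod": self.occupancy[:, 2],
            "p_high": self.occupancy[:, 3],
            "cost": self.cost,
            "qaly": self.qaly,
            "daly": self.daly,
        })
        df["cum_cost"] = df["cost"].cumsum()
        df["cum_qaly"] = df["qaly"].cumsum()
        df["cum_daly"] = df["daly"].cumsum()
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def distribution_at(self, age: int) -> HealthStateDistribution:
        idx = int(age) - MIN_AGE
        if not 0 <= idx < N_CYCLES:
            raise ValidationError(f"age {age} outside the model range")
        return HealthStateDistribution(self.occupancy[idx], int(age))


def run_cohort(setting: SettingContext | str, strategy: StrategyDefinition | str,
               params: ParameterSet) -> CohortTrace:
    """Run the deterministic 13-cycle cohort model for one setting x strategy."""
    if isinstance(setting, str):
        setting = params.setting(setting)
    if isinstance(strategy, str):
        strategy = params.strategy(strategy, setting.name)
    dist = setting.baseline_distribution
    series = [dist.occupancy]
    for age in range(MIN_AGE, MAX_AGE):
        natural = params.natural_matrix(setting.name, age)
        effective = apply_strategy(natural, strategy, setting)
        dist = advance_cohort(dist, effective)
        series.append(dist.occupancy)
    occupancies = np.vstack(series)
    economy = params.economy()
    cost, qaly, daly, totals = accrue_outcomes(
        occupancies, strategy, params.payoffs(setting.name), params.costs(setting.name),
        economy)
    return CohortTrace(
        setting=setting.name, strategy=strategy.name,
        ages=np.arange(MIN_AGE, MAX_AGE + 1), occupancy=occupancies,
        cost=cost, qaly=qaly, daly=daly, totals=totals,
        discount_rate=economy.discount_rate, label=params.provenance)


def prevalence_trajectory(trace: CohortTrace) -> pd.DataFrame:
    """Per-age total and per-state myopia prevalence (fractions)."""
    return pd.DataFrame({
        "age": trace.ages,
        "total_myopia": 1.0 - trace.occupancy[:, 0],
        "p_low": trace.occupancy[:, 1],
        "p_mod": trace.occupancy[:, 2],
        "p_high": trace.occupancy[:, 3],
    })
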