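"""Incremental cost-utility / cost-effectiveness analysis.

Strategies are ordered by ascending cost; strictly dominated options (at
least as costly and no more effective than another) and extendedly dominated
options (sequential ICER exceeding that of the next, more effective option)
are flagged and removed from the comparator chain.  Surviving strategies are
each compared with the previous surviving, cheaper one.  Ratios are kept at
full precision internally; display rounding to whole dollars is applied only
in report rendering.

Classification follows the WHO rule: a ratio below 1x per-capita GDP is
highly cost-effective, between 1x and 3x cost-effective, above 3x not
cost-effective; a negative ratio against a worse effect is dominated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .cohort import CohortTrace
from .errors import ValidationError

HIGHLY_CE = "highly_cost_effective"
CE = "cost_effective"
NOT_CE = "not_cost_effective"
DOMINATED = "dominated"


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-person lifetime (ages 6-18) outcomes of one strategy in one setting."""

    name: str
    cost: float
    qaly: float
    daly: float
    cohort_size: int = 100_000

    @classmethod
    def from_trace(cls, trace: CohortTrace, cohort_size: int = 100_000) -> "StrategyOutcome":
        t = trace.totals
        return cls(name=trace.strategy, cost=t.cost, qaly=t.qaly, daly=t.daly,
                   cohort_size=cohort_size)

    def per_cohort(self, value: float) -> float:
        return value * self.cohort_size

    def effect(self, kind: str) -> float:
        """Effect on a 'higher is better' scale: QALYs, or negated DALYs."""
        if kind == "qaly":
            return self.qaly
        if kind == "daly":
            return -self.daly
        raise ValidationError(f"effect kind must be 'qaly' or 'daly', got {kind!r}")


def compute_ratio(incremental_cost: float, incremental_effect: float) -> float:
    """Incremental cost per unit of incremental effect, sign preserved.

    A zero effect yields a signed-infinity sentinel so callers can flag
    dominance instead of dividing by zero.
    """
    if incremental_effect == 0.0:
        if incremental_cost == 0.0:
            return 0.0
        return math.copysign(math.inf, incremental_cost)
    return incremental_cost / incremental_effect


def classify(ratio: float, gdp_per_capita: float) -> str:
    """WHO threshold classification of a cost-effectiveness ratio."""
    if gdp_per_capita <= 0:
        raise ValidationError("gdp_per_capita must be positive")
    if ratio < 0:
        return DOMINATED
    if ratio < gdp_per_capita:
        return HIGHLY_CE
    if ratio <= 3.0 * gdp_per_capita:
        return CE
    return NOT_CE


@dataclass
class CEARow:
    strategy: str
    cost: float
    effect: float                 # higher-is-better scale
    comparator: str | None = None
    incremental_cost: float = float("nan")
    incremental_effect: float = float("nan")
    ratio: float = float("nan")
    dominance: str = "none"       # none | dominated | extended_dominated | duplicate
    classification: str = ""


@dataclass
class CEATable:
    """Result of an incremental analysis on one effect dimension."""

    effect_kind: str              # 'qaly' or 'daly'
    gdp_per_capita: float
    rows: list[CEARow]
    cohort_size: int = 100_000

    @property
    def frontier(self) -> list[str]:
        return [r.strategy for r in self.rows if r.dominance == "none"]

    def row(self, strategy: str) -> CEARow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise ValidationError(f"no strategy {strategy!r} in table")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            effect = -r.effect if self.effect_kind == "daly" else r.effect
            inc_eff = r.incremental_effect
            recs.append({
                "strategy": r.strategy,
                "cost_per_person": r.cost,
                f"{self.effect_kind}_per_person": effect,
                "comparator": r.comparator or "",
                "incremental_cost_per_cohort": r.incremental_cost * self.cohort_size
                if not math.isnan(r.incremental_cost) else float("nan"),
                f"incremental_{self.effect_kind}_per_cohort":
                    inc_eff * self.cohort_size if not math.isnan(inc_eff) else float("nan"),
                "ratio": r.ratio,
                "dominance": r.dominance,
                "classification": r.classification,
            })
        return pd.DataFrame.from_records(recs)


def incremental_analysis(outcomes: list[StrategyOutcome], gdp_per_capita: float,
                         effect: str = "qaly") -> CEATable:
    """Full incremental analysis with strict and extended dominance.

    Dominated strategies are excluded from the comparator chain but still
    reported with their (possibly negative or infinite) ratio against the
    previous non-dominated, cheaper strategy for transparency.
    """
    if len(outcomes) < 2:
        raise ValidationError("incremental analysis needs at least 2 strategies")
    names = [o.name for o in outcomes]
    if len(set(names)) != len(names):
        raise ValidationError(f"strategy names must be distinct, got {names}")

    rows = [CEARow(strategy=o.name, cost=o.cost, effect=o.effect(effect))
            for o in outcomes]
    rows.sort(key=lambda r: (r.cost, -r.effect))

    # exact duplicates on the (cost, effect) plane
    for i, r in enumerate(rows):
        for s in rows[:i]:
            if s.dominance in ("none",) and s.cost == r.cost and s.effect == r.effect:
                r.dominance = "duplicate"
                break

    # strict dominance: some other strategy is no more costly and no less
    # effective, with at least one strict inequality
    for r in rows:
        if r.dominance != "none":
            continue
        for s in rows:
            if s is r or s.dominance == "dominated":
                continue
            if (s.cost <= r.cost and s.effect >= r.effect
                    and (s.cost < r.cost or s.effect > r.effect)):
                r.dominance = "dominated"
                break

    # extended dominance: iteratively remove options whose sequential ICER
    # exceeds that of the next surviving, more effective option
    while True:
        live = [r for r in rows if r.dominance == "none"]
        changed = False
        for k in range(1, len(live) - 1):
            icer_prev = compute_ratio(live[k].cost - live[k - 1].cost,
                                      live[k].effect - live[k - 1].effect)
            icer_next = compute_ratio(live[k + 1].cost - live[k].cost,
                                      live[k + 1].effect - live[k].effect)
            if icer_prev >= icer_next:
                live[k].dominance = "extended_dominated"
                changed = True
                break
        if not changed:
            break

    # comparator chain over survivors; dominated rows compared to the
    # previous survivor for transparency
    last_survivor: CEARow | None = None
    for r in rows:
        if last_survivor is not None:
            r.comparator = last_survivor.strategy
            r.incremental_cost = r.cost - last_survivor.cost
            r.incremental_effect = r.effect - last_survivor.effect
            r.ratio = compute_ratio(r.incremental_cost, r.incremental_effect)
            if r.dominance == "none":
                r.classification = (DOMINATED if r.incremental_effect < 0
                                    else classify(r.ratio, gdp_per_capita))
            else:
                r.classification = DOMINATED
        if r.dominance == "none":
            last_survivor = r

    return CEATable(effect_kind=effect, gdp_per_capita=gdp_per_capita, rows=rows,
                    cohort_size=outcomes[0].cohort_size)


def full_cea(outcomes: list[StrategyOutcome], gdp_per_capita: float
             ) -> tuple[CEATable, CEATable, pd.DataFrame]:
    """Run the analysis on both effect dimensions and merge into one table.

    Returns the QALY table (ICURs), the DALY table (ICERs) and a combined
    frame shaped like a base-case results table.  Emits a warning when the
    two dominance analyses disagree on which strategies survive.
    """
    icur = incremental_analysis(outcomes, gdp_per_capita, effect="qaly")
    icer = incremental_analysis(outcomes, gdp_per_capita, effect="daly")
    if icur.frontier != icer.frontier:
        warnings.warn(
            "extended-dominance frontier differs between QALY and DALY coordinates: "
            f"{icur.frontier} vs {icer.frontier}", stacklevel=2)
    # the combined table follows the base-case presentation convention: every
    # strategy is compared with the previous one in cost order, with the
    # rigorous dominance flags reported alongside
    ordered = sorted(outcomes, key=lambda o: (o.cost, -o.qaly))
    recs = []
    for i, o in enumerate(ordered):
        rq, rd = icur.row(o.name), icer.row(o.name)
        rec = {
            "strategy": o.name,
            "cost_per_person": o.cost,
            "qaly_per_person": o.qaly,
            "daly_per_person": o.daly,
            "comparator": "",
            "incremental_cost_per_cohort": float("nan"),
            "incremental_qaly_per_cohort": float("nan"),
            "icur": float("nan"),
            "icur_class": "",
            "incremental_daly_averted_per_cohort": float("nan"),
            "icer": float("nan"),
            "icer_class": "",
            "dominance_qaly": rq.dominance,
            "dominance_daly": rd.dominance,
        }
        if i > 0:
            prev = ordered[i - 1]
            d_cost = o.cost - prev.cost
            d_qaly = o.qaly - prev.qaly
            d_daly_averted = prev.daly - o.daly
            rec.update({
                "comparator": prev.name,
                "incremental_cost_per_cohort": d_cost * o.cohort_size,
                "incremental_qaly_per_cohort": d_qaly * o.cohort_size,
                "icur": compute_ratio(d_cost, d_qaly),
                "incremental_daly_averted_per_cohort": d_daly_averted * o.cohort_size,
                "icer": compute_ratio(d_cost, d_daly_averted),
            })
            rec["icur_class"] = (DOMINATED if d_qaly < 0
                                 else classify(rec["icur"], gdp_per_capita))
            rec["icer_class"] = (DOMINATED if d_daly_averted < 0
                                 else classify(rec["icer"], gdp_per_capita))
        recs.append(rec)
    return icur, icer, pd.DataFrame.from_records(recs)
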