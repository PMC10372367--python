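"""Uncertainty analysis: one-way (tornado), probabilistic (PSA/CEAC), subgroups.

One-way analysis re-runs the full deterministic pipeline with a single
scalar moved to base*(1-f) and base*(1+f).  Probabilistic analysis assigns
beta distributions to bounded quantities (probabilities, compliances, test
characteristics, utility decrements, disability weights) and gamma
distributions to cost lines, with moments matched so the mean reproduces the
base value; the model is re-run for every Monte-Carlo draw and
cost-effectiveness acceptability is summarised with the net-monetary-benefit
argmax rule.  Dispersion defaults (beta effective sample size 100, gamma
coefficient of variation 0.2) are conventional PSA practice and are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import StrategyOutcome, incremental_analysis
from .cohort import run_cohort
from .errors import ConfigurationError, ValidationError
from .params import ParameterSet
from .states import MAX_AGE, MIN_AGE, N_CYCLES
from .strategies import STRATEGY_NAMES, StrategyDefinition

logger = logging.getLogger(__name__)

#: cumulative order of the perfect-compliance subgroup chain
SUBGROUP_FIELDS = ("outdoor_compliance", "coverage", "spectacle_compliance",
                   "referral_compliance")

#: document paths whose values are probabilities and must stay in [0, 1]
_PROBABILITY_MARKERS = ("transitions", "compliance", "screening_test", "payoffs",
                        "effects", "education_exposure", "baseline")


@dataclass(frozen=True)
class ModelBundle:
    """Everything one sensitivity run needs: parameters, setting, strategies."""

    params: ParameterSet
    setting: str
    strategies: tuple[str, ...] = STRATEGY_NAMES

    def outcomes(self, params: ParameterSet | None = None) -> list[StrategyOutcome]:
        p = params if params is not None else self.params
        ctx = p.setting(self.setting)
        return [StrategyOutcome.from_trace(run_cohort(ctx, s, p), ctx.cohort_size)
                for s in self.strategies]

    @property
    def gdp_per_capita(self) -> float:
        return self.params.setting(self.setting).gdp_per_capita


# --------------------------------------------------------------- percentiles
def percentile_interval(samples, q_low: float = 2.5, q_high: float = 97.5
                        ) -> tuple[float, float]:
    """Empirical (2.5th, 97.5th) percentile interval.

    Uses linear interpolation between order statistics (the common "type 7"
    convention); e.g. samples 1..100 give (3.475, 97.525).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValidationError("percentile interval of an empty sample")
    lo, hi = np.percentile(arr, [q_low, q_high], method="linear")
    return float(lo), float(hi)


# ------------------------------------------------------------------- one-way
@dataclass(frozen=True)
class OneWayRange:
    parameter: str
    bound_fraction: float
    base_value: float
    base_ratio: float
    low_value: float
    high_value: float
    low_ratio: float
    high_ratio: float

    @property
    def width(self) -> float:
        return abs(self.high_ratio - self.low_ratio)


def _icur_for(bundle: ModelBundle, params: ParameterSet, strategy: str) -> float:
    table = incremental_analysis(bundle.outcomes(params), bundle.gdp_per_capita,
                                 effect="qaly")
    return table.row(strategy).ratio


def one_way(parameter_path: str, bound_fraction: float, bundle: ModelBundle,
            strategy: str = "digital") -> OneWayRange:
    """Re-run the deterministic pipeline at base*(1-f) and base*(1+f).

    The reported ratio is the ICUR of ``strategy`` against its comparator in
    the incremental analysis.  Perturbed probabilities leaving [0, 1] are
    clipped with a logged warning.
    """
    if bound_fraction not in (0.0, 0.10, 0.20):
        logger.warning("unconventional one-way bound fraction %s (expected 0.10 or 0.20)",
                       bound_fraction)
    base = bundle.params.get_path(parameter_path)
    if not isinstance(base, (int, float)) or isinstance(base, bool):
        raise ConfigurationError(f"{parameter_path!r} is not a scalar parameter")
    base = float(base)
    is_probability = any(m in parameter_path for m in _PROBABILITY_MARKERS)
    ratios = {}
    values = {}
    for side, factor in (("low", 1.0 - bound_fraction), ("high", 1.0 + bound_fraction)):
        value = base * factor
        if is_probability and not 0.0 <= value <= 1.0:
            clipped = min(max(value, 0.0), 1.0)
            logger.warning("one-way bound %s for %s clipped from %.6g to %.6g",
                           side, parameter_path, value, clipped)
            value = clipped
        perturbed = bundle.params.copy()
        perturbed.set_path(parameter_path, value)
        values[side] = value
        ratios[side] = _icur_for(bundle, perturbed, strategy)
    return OneWayRange(
        parameter=parameter_path, bound_fraction=bound_fraction, base_value=base,
        base_ratio=_icur_for(bundle, bundle.params, strategy),
        low_value=values["low"], high_value=values["high"],
        low_ratio=ratios["low"], high_ratio=ratios["high"])


def tornado(parameter_paths: list[str], bundle: ModelBundle,
            probability_fraction: float = 0.10, cost_fraction: float = 0.20,
            strategy: str = "digital") -> pd.DataFrame:
    """One-way ranges for many parameters, ordered by range width (tornado).

    Probabilities float by +/-10% of base, cost lines by +/-20% (the two
    conventional ranges; assignment per class is configurable).
    """
    rows = []
    for path in parameter_paths:
        frac = cost_fraction if ".costs." in path else probability_fraction
        r = one_way(path, frac, bundle, strategy=strategy)
        rows.append({"parameter": r.parameter, "bound_fraction": r.bound_fraction,
                     "low_icur": r.low_ratio, "high_icur": r.high_ratio,
                     "range": r.width})
    df = pd.DataFrame.from_records(rows)
    return df.sort_values("range", ascending=False, ignore_index=True)


# ----------------------------------------------------------------------- PSA
@dataclass(frozen=True)
class PSAConfig:
    iterations: int = 10_000
    seed: int = 0
    beta_ess: float | None = 100.0   # alpha+beta; None -> degenerate point mass
    gamma_cv: float = 0.2            # coefficient of variation; 0 -> point mass

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.beta_ess is not None and self.beta_ess <= 0:
            raise ValidationError("beta_ess must be positive or None")
        if self.gamma_cv < 0:
            raise ValidationError("gamma_cv must be non-negative")


def _sample_beta(rng: np.random.Generator, mean: float, ess: float | None,
                 size: int, name: str = "") -> np.ndarray:
    """Beta draws with the mean moment-matched to the base value.

    Structural 0/1 values are constants of the model, not uncertain
    quantities, and are returned as point masses.
    """
    if not 0.0 <= mean <= 1.0:
        raise ConfigurationError(f"beta parameter {name!r} has base value {mean} outside [0, 1]")
    if ess is None or mean in (0.0, 1.0):
        return np.full(size, mean)
    return rng.beta(mean * ess, (1.0 - mean) * ess, size=size)


def _sample_gamma(rng: np.random.Generator, mean: float, cv: float, size: int,
                  name: str = "") -> np.ndarray:
    if mean < 0:
        raise ConfigurationError(f"gamma parameter {name!r} has negative base value {mean}")
    if cv <= 0 or mean == 0.0:
        return np.full(size, mean)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean / shape, size=size)


@dataclass
class PSAResult:
    strategies: tuple[str, ...]
    costs: np.ndarray   # (iterations, n_strategies) per person
    qalys: np.ndarray
    dalys: np.ndarray
    seed: int
    iterations: int
    gdp_per_capita: float

    def ce_probability(self, willingness_to_pay: float, effect: str = "qaly"
                       ) -> dict[str, float]:
        """Fraction of draws in which each strategy maximises net monetary benefit."""
        eff = self.qalys if effect == "qaly" else -self.dalys
        nmb = eff * willingness_to_pay - self.costs
        best = np.argmax(nmb, axis=1)
        return {s: float(np.mean(best == j)) for j, s in enumerate(self.strategies)}

    def ceac(self, wtp_grid: np.ndarray | None = None, effect: str = "qaly"
             ) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
        if wtp_grid is None:
            wtp_grid = np.linspace(0.0, 4.0 * self.gdp_per_capita, 101)
        recs = []
        for tau in wtp_grid:
            probs = self.ce_probability(float(tau), effect=effect)
            recs.append({"wtp": float(tau), **{f"p_{s}": probs[s] for s in self.strategies}})
        return pd.DataFrame.from_records(recs)

    def percentiles(self) -> pd.DataFrame:
        """2.5th/97.5th percentile intervals of cost, QALY, DALY per strategy."""
        recs = []
        for j, s in enumerate(self.strategies):
            rec = {"strategy": s}
            for label, arr in (("cost", self.costs), ("qaly", self.qalys),
                               ("daly", self.dalys)):
                lo, hi = percentile_interval(arr[:, j])
                rec[f"{label}_p2.5"] = lo
                rec[f"{label}_p97.5"] = hi
            recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def draws_frame(self) -> pd.DataFrame:
        """One row per iteration per strategy (for CSV export)."""
        recs = []
        for j, s in enumerate(self.strategies):
            recs.append(pd.DataFrame({
                "iteration": np.arange(self.iterations), "strategy": s,
                "cost": self.costs[:, j], "qaly": self.qalys[:, j],
                "daly": self.dalys[:, j]}))
        return pd.concat(recs, ignore_index=True)


def run_psa(config: PSAConfig, bundle: ModelBundle) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis, vectorised over draws.

    All strategies share each draw (joint resampling), so parameters common
    to several strategies stay correlated across them.  Baseline state
    prevalences are treated as data, not resampled.
    """
    p = bundle.params
    rng = np.random.default_rng(config.seed)
    n = config.iterations
    ess, cv = config.beta_ess, config.gamma_cv
    setting = bundle.setting
    blk = p.data["settings"][setting]
    ages = list(range(MIN_AGE, MAX_AGE))

    def beta(mean, name):
        return _sample_beta(rng, float(mean), ess, n, name)

    # natural history
    trans = blk["transitions"]
    onset = np.column_stack([beta(trans["onset"][str(a)], f"onset@{a}") for a in ages])
    p1 = np.column_stack([beta(trans["low_to_moderate"][str(a)], f"low_to_moderate@{a}")
                          for a in ages])
    p2 = np.column_stack([beta(trans["moderate_to_high"][str(a)], f"moderate_to_high@{a}")
                          for a in ages])
    # cascade and effects; strategies with compliance overrides get their own
    # draws for the overridden fields, everything else is shared (correlated)
    sens = beta(p.data["screening_test"]["sensitivity"], "sensitivity")
    spec = beta(p.data["screening_test"]["specificity"], "specificity")
    _field_draws: dict[tuple[str, float], np.ndarray] = {}

    def cascade_draw(field_name: str, value: float) -> np.ndarray:
        key = (field_name, value)
        if key not in _field_draws:
            _field_draws[key] = beta(value, field_name)
        return _field_draws[key]

    strat_cascade = {}
    for strat_name in bundle.strategies:
        c = p.strategy(strat_name, setting).cascade
        strat_cascade[strat_name] = {
            "coverage": cascade_draw("coverage", c.coverage),
            "referral": cascade_draw("referral", c.referral_compliance),
            "spectacles": cascade_draw("spectacles", c.spectacle_compliance),
            "outdoor": cascade_draw("outdoor", c.outdoor_compliance),
        }
    m_onset = beta(p._resolve(p.data["effects"]["outdoor"]["onset_rate_multiplier"], setting),
                   "onset multiplier")
    m_prog = beta(p._resolve(p.data["effects"]["spectacles"]["progression_rate_multiplier"],
                             setting), "progression multiplier")
    exposures = {
        name: beta(p._resolve(sblk.get("education_exposure", 0.0), setting),
                   f"education_exposure[{name}]")
        for name, sblk in p.data["strategies"].items()}
    channels = {name: sblk.get("education_channel", "none")
                for name, sblk in p.data["strategies"].items()}
    # payoffs: utilities sampled via their decrement from full health
    pay = p.data["payoffs"]
    util = np.column_stack([
        1.0 - _sample_beta(rng, 1.0 - p._resolve(pay["utility"][s], setting), ess, n,
                           f"utility[{s}]")
        for s in ("non", "low", "moderate", "high")])
    dw = np.column_stack([beta(p._resolve(pay["disability_weight"][s], setting),
                               f"disability_weight[{s}]")
                          for s in ("non", "low", "moderate", "high")])
    # costs
    costs = {k: _sample_gamma(rng, float(v), cv, n, k)
             for k, v in blk["costs"].items() if k != "capital_share"}

    disc = (1.0 + p.economy().discount_rate) ** (-np.arange(N_CYCLES, dtype=float))
    baseline = p.setting(setting).baseline_distribution.occupancy

    n_strat = len(bundle.strategies)
    out_cost = np.zeros((n, n_strat))
    out_qaly = np.zeros((n, n_strat))
    out_daly = np.zeros((n, n_strat))

    for j, strat_name in enumerate(bundle.strategies):
        expo = exposures[strat_name]
        channel = channels[strat_name]
        casc = strat_cascade[strat_name]
        coverage, referral = casc["coverage"], casc["referral"]
        spectacles, outdoor = casc["spectacles"], casc["outdoor"]
        treat_reach = coverage * sens * referral * spectacles
        f_prog = 1.0 - treat_reach * (1.0 - m_prog)
        f_on = 1.0 - expo * outdoor * (1.0 - m_onset)
        occ = np.tile(baseline, (n, 1))
        for k in range(N_CYCLES):
            myopic = occ[:, 1:].sum(axis=1)
            # payoffs and event costs accrue at this age point
            out_qaly[:, j] += disc[k] * (occ * util).sum(axis=1)
            out_daly[:, j] += disc[k] * (occ * dw).sum(axis=1)
            referred = (myopic * coverage * sens
                        + occ[:, 0] * coverage * (1.0 - spec)) * referral
            treated = myopic * treat_reach
            cycle_cost = (coverage * costs["screening_per_test"]
                          + (costs["education_traditional"] if channel == "traditional" else 0.0)
                          + (costs["education_digital"] if channel == "digital" else 0.0)
                          + referred * costs["hospital_examination"]
                          + treated * costs["treatment_annual"]
                          + expo * outdoor * costs.get("outdoor_program", 0.0))
            out_cost[:, j] += disc[k] * cycle_cost
            if k < N_CYCLES - 1:
                on = onset[:, k] * f_on
                q1 = p1[:, k] * f_prog
                q2 = p2[:, k] * f_prog
                nxt = np.empty_like(occ)
                nxt[:, 0] = occ[:, 0] * (1.0 - on)
                nxt[:, 1] = occ[:, 0] * on + occ[:, 1] * (1.0 - q1)
                nxt[:, 2] = occ[:, 1] * q1 + occ[:, 2] * (1.0 - q2)
                nxt[:, 3] = occ[:, 2] * q2 + occ[:, 3]
                occ = nxt

    return PSAResult(strategies=tuple(bundle.strategies), costs=out_cost,
                     qalys=out_qaly, dalys=out_daly, seed=config.seed,
                     iterations=n, gdp_per_capita=bundle.gdp_per_capita)


# ----------------------------------------------------------------- subgroups
def subgroup_scenarios(params: ParameterSet, setting: str,
                       fields: tuple[str, ...] = SUBGROUP_FIELDS,
                       base_strategy: str = "digital",
                       reference_strategy: str = "traditional") -> pd.DataFrame:
    """Sequential perfect-compliance variants of the digital strategy.

    Starting from the traditional strategy as reference, compliance fields
    of ``base_strategy`` are raised to 100% cumulatively in the given order
    (outdoor activity, vision-test coverage, spectacles, hospital
    examination); each variant is compared with the previous row.  Values
    are per person: cost, DALY, incremental cost, incremental DALYs averted
    and the resulting ICER.
    """
    ctx = params.setting(setting)
    rows: list[dict] = []

    def add_row(name: str, strategy: StrategyDefinition, base_value: float | None) -> None:
        trace = run_cohort(ctx, strategy, params)
        rec = {"scenario": name, "base_case_value": base_value,
               "cost_per_person": trace.totals.cost, "daly_per_person": trace.totals.daly,
               "qaly_per_person": trace.totals.qaly}
        if rows:
            prev = rows[-1]
            rec["comparator"] = prev["scenario"]
            rec["incremental_cost_per_person"] = rec["cost_per_person"] - prev["cost_per_person"]
            rec["incremental_daly_averted_per_person"] = (prev["daly_per_person"]
                                                          - rec["daly_per_person"])
            dcost, dav = rec["incremental_cost_per_person"], rec["incremental_daly_averted_per_person"]
            rec["icer"] = dcost / dav if dav != 0 else float("inf") * np.sign(dcost or 1)
        rows.append(rec)

    add_row(reference_strategy, params.strategy(reference_strategy, setting), None)
    variant = params.strategy(base_strategy, setting)
    labels = {"outdoor_compliance": "perfect_outdoor_activity",
              "coverage": "perfect_vision_test_coverage",
              "spectacle_compliance": "perfect_spectacles",
              "referral_compliance": "perfect_hospital_examination"}
    for field_name in fields:
        base_value = getattr(variant.cascade, field_name)
        variant = variant.with_perfect(field_name)
        add_row(labels.get(field_name, f"perfect_{field_name}"), variant, base_value)
    df = pd.DataFrame.from_records(rows)
    return df
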