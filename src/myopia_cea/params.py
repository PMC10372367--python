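"""Parameter-set container and file I/O.

A parameter set is a single structured document (JSON or YAML) holding
everything one model run needs: the four-state definitions are implicit,
while the file supplies per-age transition probabilities, strategy
definitions (education channel and exposure), per-setting compliance and
cost schedules, utility/disability weights, and the economic context.

All probabilities are decimals (fractions, not percents); all costs are in
2021 USD unless the ``meta.currency`` field says CNY, in which case they are
converted on load using ``economics.exchange_rate``.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .economics import CostSchedule, EconomyContext, PayoffSchedule, convert_currency
from .errors import ConfigurationError
from .states import MAX_AGE, MIN_AGE, HealthStateDistribution, STATE_LABELS
from .strategies import (InterventionEffect, ScreeningCascade, SettingContext,
                         StrategyDefinition)
from .transitions import TransitionMatrix, progression_matrix

SURROGATE_LABEL = "calibrated surrogate, not original appendix values"

_TRANSITION_KEYS = ("onset", "low_to_moderate", "moderate_to_high")
_COST_KEYS = ("screening_per_test", "education_traditional", "education_digital",
              "hospital_examination", "treatment_annual", "outdoor_program")


class ParameterSet:
    """In-memory view of a model parameter file with typed accessors."""

    def __init__(self, data: dict[str, Any]):
        self.data = data
        self.validate()

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: parameter file must be a mapping")
        currency = data.get("meta", {}).get("currency", "USD")
        if currency == "CNY":
            rate = data.get("economics", {}).get("exchange_rate")
            if not rate:
                raise ConfigurationError(
                    f"{path}: costs are in CNY but no economics.exchange_rate is supplied")
            for setting in data.get("settings", {}).values():
                for k, v in setting.get("costs", {}).items():
                    setting["costs"][k] = convert_currency(v, rate)
            data["meta"]["currency"] = "USD"
        elif currency != "USD":
            raise ConfigurationError(f"{path}: unsupported currency {currency!r}")
        return cls(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.data, sort_keys=False))
        else:
            path.write_text(json.dumps(self.data, indent=1, sort_keys=False) + "\n")

    def copy(self) -> "ParameterSet":
        return ParameterSet(copy.deepcopy(self.data))

    # ---------------------------------------------------------- validation
    def validate(self) -> None:
        d = self.data
        for block in ("meta", "economics", "screening_test", "effects", "payoffs",
                      "strategies", "settings"):
            if block not in d:
                raise ConfigurationError(f"parameter file missing block {block!r}")
        if d["meta"].get("currency", "USD") != "USD":
            raise ConfigurationError("in-memory parameter sets must carry USD costs")
        if "cost_year" not in d["meta"]:
            raise ConfigurationError("meta.cost_year is required")
        for name in d["strategies"]:
            for setting_name in d["settings"]:
                self.strategy(name, setting_name)
        for setting_name in d["settings"]:
            self.setting(setting_name)
            self.costs(setting_name)
            self.payoffs(setting_name)
            for age in range(MIN_AGE, MAX_AGE):
                self.natural_matrix(setting_name, age)
        self.economy()

    # ----------------------------------------------------------- accessors
    @property
    def label(self) -> str:
        return str(self.data["meta"].get("label", ""))

    @property
    def provenance(self) -> str:
        return str(self.data["meta"].get("provenance", ""))

    @property
    def is_surrogate(self) -> bool:
        return SURROGATE_LABEL in self.provenance

    @property
    def setting_names(self) -> tuple[str, ...]:
        return tuple(self.data["settings"])

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(self.data["strategies"])

    def _setting_block(self, name: str) -> dict[str, Any]:
        try:
            return self.data["settings"][name]
        except KeyError:
            raise ConfigurationError(f"unknown setting {name!r}") from None

    def setting(self, name: str) -> SettingContext:
        blk = self._setting_block(name)
        base = blk["baseline"]
        dist = HealthStateDistribution.from_myopia_prevalences(
            low=base["low"], moderate=base["moderate"], high=base["high"], age=6)
        return SettingContext(
            name=name, baseline_distribution=dist,
            gdp_per_capita=float(blk["gdp_per_capita"]),
            cohort_size=int(self.data["economics"].get("cohort_size", 100_000)))

    def natural_matrix(self, setting_name: str, age: int) -> TransitionMatrix:
        blk = self._setting_block(setting_name)
        trans = blk["transitions"]
        if "matrix" in trans:
            mats = trans["matrix"]
            key = str(age)
            if key not in mats:
                raise ConfigurationError(
                    f"setting {setting_name!r}: no transition matrix for age {age}")
            return TransitionMatrix(age=age, probabilities=np.asarray(mats[key], dtype=float))
        probs = {}
        for k in _TRANSITION_KEYS:
            table = trans.get(k, {})
            key = str(age)
            if key not in table:
                raise ConfigurationError(
                    f"setting {setting_name!r}: no {k} probability for age {age}")
            probs[k] = float(table[key])
        return progression_matrix(age, probs["onset"], probs["low_to_moderate"],
                                  probs["moderate_to_high"])

    def _resolve(self, value: Any, setting_name: str) -> float:
        if isinstance(value, dict):
            try:
                return float(value[setting_name])
            except KeyError:
                raise ConfigurationError(
                    f"no value for setting {setting_name!r} in {value!r}") from None
        return float(value)

    def cascade(self, setting_name: str) -> ScreeningCascade:
        blk = self._setting_block(setting_name)
        comp = blk["compliance"]
        test = self.data["screening_test"]
        return ScreeningCascade(
            coverage=float(comp["coverage"]),
            sensitivity=float(test["sensitivity"]),
            specificity=float(test["specificity"]),
            referral_compliance=float(comp["referral"]),
            spectacle_compliance=float(comp["spectacles"]),
            outdoor_compliance=float(comp["outdoor"]),
        )

    _OVERRIDE_FIELDS = {"coverage": "coverage", "referral": "referral_compliance",
                        "spectacles": "spectacle_compliance", "outdoor": "outdoor_compliance"}

    def strategy(self, name: str, setting_name: str) -> StrategyDefinition:
        try:
            blk = self.data["strategies"][name]
        except KeyError:
            raise ConfigurationError(f"unknown strategy {name!r}") from None
        eff = self.data["effects"]
        # effect multipliers may be per-setting: the treatment portfolio and
        # quality of follow-up care differ between rural and urban settings
        outdoor = InterventionEffect(
            "outdoor", onset_rate_multiplier=self._resolve(
                eff["outdoor"]["onset_rate_multiplier"], setting_name))
        treatment = InterventionEffect(
            "spectacles", progression_rate_multiplier=self._resolve(
                eff["spectacles"]["progression_rate_multiplier"], setting_name))
        cascade = self.cascade(setting_name)
        overrides = blk.get("compliance_overrides", {})
        if overrides:
            from dataclasses import replace
            unknown = set(overrides) - set(self._OVERRIDE_FIELDS)
            if unknown:
                raise ConfigurationError(
                    f"strategy {name!r}: unknown compliance overrides {sorted(unknown)}")
            resolved = {self._OVERRIDE_FIELDS[k]: self._resolve(v, setting_name)
                        for k, v in overrides.items()}
            cascade = replace(cascade, **resolved)
        return StrategyDefinition(
            name=name,
            cascade=cascade,
            education_channel=blk.get("education_channel", "none"),
            education_exposure=self._resolve(blk.get("education_exposure", 0.0), setting_name),
            outdoor_effect=outdoor,
            treatment_effect=treatment,
        )

    def payoffs(self, setting_name: str | None = None) -> PayoffSchedule:
        """Utility and disability weights, resolved for a setting.

        State weights may be scalars or per-setting mappings: the effective
        weight of a myopic state is a mixture of corrected and uncorrected
        vision-impairment weights, and correction access differs between
        rural and urban populations.
        """
        p = self.data["payoffs"]
        if setting_name is None:
            setting_name = next(iter(self.data["settings"]))

        def resolve(block: dict, state: str) -> float:
            try:
                return self._resolve(block[state], setting_name)
            except KeyError:
                raise ConfigurationError(
                    f"payoffs block missing weight for state {state!r}") from None

        u = np.array([resolve(p["utility"], s) for s in STATE_LABELS], dtype=float)
        d = np.array([resolve(p["disability_weight"], s) for s in STATE_LABELS], dtype=float)
        return PayoffSchedule(utility=u, disability_weight=d)

    def costs(self, setting_name: str) -> CostSchedule:
        blk = self._setting_block(setting_name)
        c = blk["costs"]
        unknown = set(c) - set(_COST_KEYS) - {"capital_share"}
        if unknown:
            raise ConfigurationError(
                f"setting {setting_name!r}: unknown cost lines {sorted(unknown)}")
        return CostSchedule(**{k: float(v) for k, v in c.items()})

    def economy(self) -> EconomyContext:
        e = self.data["economics"]
        return EconomyContext(
            exchange_rate=float(e.get("exchange_rate", 6.45)),
            cost_adjustment_rate=float(e.get("cost_adjustment_rate", 0.05)),
            discount_rate=float(e.get("discount_rate", 0.05)),
            national_gdp_per_capita=float(e.get("national_gdp_per_capita", 12_551)),
            urbanization_rate=float(e.get("urbanization_rate", 0.65)),
            urban_rural_income_ratio=float(e.get("urban_rural_income_ratio", 2.5)),
            half_cycle_correction=bool(e.get("half_cycle_correction", False)),
        )

    # ------------------------------------------------------ path utilities
    def get_path(self, path: str) -> Any:
        node: Any = self.data
        for part in path.split("."):
            try:
                node = node[part]
            except (KeyError, TypeError):
                raise ConfigurationError(f"no parameter at path {path!r}") from None
        return node

    def set_path(self, path: str, value: Any) -> None:
        parts = path.split(".")
        node: Any = self.data
        for part in parts[:-1]:
            try:
                node = node[part]
            except (KeyError, TypeError):
                raise ConfigurationError(f"no parameter at path {path!r}") from None
        if parts[-1] not in node:
            raise ConfigurationError(f"no parameter at path {path!r}")
        node[parts[-1]] = value

    def scalar_paths(self) -> list[str]:
        """Dot paths of every numeric scalar in the document (for sensitivity)."""
        out: list[str] = []

        def walk(node: Any, prefix: str) -> None:
            if isinstance(node, dict):
                for k, v in node.items():
                    walk(v, f"{prefix}.{k}" if prefix else str(k))
            elif isinstance(node, (int, float)) and not isinstance(node, bool):
                out.append(prefix)

        walk(self.data, "")
        return out


def load_reference_parameters() -> ParameterSet:
    """Load the packaged calibrated surrogate parameter set."""
    path = Path(__file__).parent / "data" / "calibrated_params.json"
    if not path.exists():
        raise ConfigurationError(
            "packaged calibrated parameter fixture not found; run the calibrate "
            "command to regenerate it")
    return ParameterSet.from_file(path)
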