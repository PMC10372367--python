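"""Cohort engine: strategy application, full runs, trajectory properties."""

import copy

import numpy as np
import pytest
from hypothesis import given, strategies as st

import myopia_cea as m
from myopia_cea.errors import ConfigurationError
from myopia_cea.params import ParameterSet


def perturbed_params(base: ParameterSet, seed: int) -> ParameterSet:
    """Random structurally-valid variation of a parameter set."""
    rng = np.random.default_rng(seed)
    p = base.copy()
    for blk in p.data["settings"].values():
        for table in blk["transitions"].values():
            for k in table:
                table[k] = float(np.clip(table[k] * rng.uniform(0.5, 1.5), 0.0, 0.95))
    return ParameterSet(p.data)


class TestApplyStrategy:
    def test_zero_reach_returns_natural_history(self, guess_params):
        natural = guess_params.natural_matrix("rural", 8)
        strategy = guess_params.strategy("school_screening", "rural")
        # screening-only: no education channel, so onset is untouched; zero the
        # treatment cascade too
        from dataclasses import replace
        strategy = replace(strategy, cascade=replace(strategy.cascade,
                                                     referral_compliance=0.0))
        out = m.apply_strategy(natural, strategy)
        assert np.allclose(out.probabilities, natural.probabilities, atol=1e-15)

    def test_full_cascade_halves_onset(self):
        natural = m.progression_matrix(7, onset=0.10, low_to_moderate=0.05,
                                       moderate_to_high=0.02)
        cascade = m.ScreeningCascade(coverage=1.0, sensitivity=1.0, specificity=1.0,
                                     referral_compliance=1.0, spectacle_compliance=1.0,
                                     outdoor_compliance=1.0)
        strategy = m.StrategyDefinition(
            name="digital", cascade=cascade, education_channel="digital",
            education_exposure=1.0,
            outdoor_effect=m.InterventionEffect("outdoor", onset_rate_multiplier=0.5),
            treatment_effect=m.InterventionEffect("spectacles",
                                                  progression_rate_multiplier=1.0))
        out = m.apply_strategy(natural, strategy)
        assert out.probabilities[0, 1] == pytest.approx(0.05)
        assert out.probabilities[0, 0] == pytest.approx(0.95)

    def test_reach_formula_cell_by_cell(self, ref_params):
        """Effective matrix equals a scalar-by-scalar oracle recomputation."""
        strategy = ref_params.strategy("digital", "rural")
        natural = ref_params.natural_matrix("rural", 10)
        out = m.apply_strategy(natural, strategy)
        c = strategy.cascade
        reach_onset = strategy.education_exposure * c.outdoor_compliance
        reach_treat = (c.coverage * c.sensitivity * c.referral_compliance
                       * c.spectacle_compliance)
        f_on = 1 - reach_onset * (1 - strategy.outdoor_effect.onset_rate_multiplier)
        f_tr = 1 - reach_treat * (1 - strategy.treatment_effect.progression_rate_multiplier)
        nat = natural.probabilities
        assert out.probabilities[0, 1] == pytest.approx(nat[0, 1] * f_on, abs=1e-15)
        assert out.probabilities[1, 2] == pytest.approx(nat[1, 2] * f_tr, abs=1e-15)
        assert out.probabilities[2, 3] == pytest.approx(nat[2, 3] * f_tr, abs=1e-15)
        assert np.allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-12)


class TestRunCohort:
    def test_matches_independent_matrix_multiply_oracle(self, guess_params):
        """Trace occupancies agree with a from-scratch vector-matrix recursion."""
        for seed in range(5):
            params = perturbed_params(guess_params, seed)
            for setting in ("rural", "urban"):
                for name in m.STRATEGY_NAMES:
                    strategy = params.strategy(name, setting)
                    trace = m.run_cohort(setting, name, params)
                    occ = params.setting(setting).baseline_distribution.occupancy.copy()
                    f_on = strategy.onset_factor()
                    f_tr = strategy.progression_factor()
                    for k, age in enumerate(range(6, 18)):
                        assert np.allclose(trace.occupancy[k], occ, atol=1e-12)
                        nat = params.natural_matrix(setting, age).probabilities.copy()
                        nat[0, 1] *= f_on
                        nat[0, 0] = 1 - nat[0, 1]
                        nat[1, 2] *= f_tr
                        nat[1, 1] = 1 - nat[1, 2]
                        nat[2, 3] *= f_tr
                        nat[2, 2] = 1 - nat[2, 3]
                        occ = occ @ nat
                    assert np.allclose(trace.occupancy[-1], occ, atol=1e-12)

    def test_runs_are_bit_identical(self, ref_params):
        a = m.run_cohort("rural", "digital", ref_params)
        b = m.run_cohort("rural", "digital", ref_params)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.cost, b.cost)
        assert a.totals == b.totals

    def test_zero_transitions_keep_baseline(self, guess_params):
        p = guess_params.copy()
        for blk in p.data["settings"].values():
            for table in blk["transitions"].values():
                for k in table:
                    table[k] = 0.0
        trace = m.run_cohort("rural", "school_screening", ParameterSet(p.data))
        assert np.allclose(trace.occupancy, trace.occupancy[0], atol=1e-15)
        traj = m.prevalence_trajectory(trace)
        assert traj["total_myopia"].nunique() == 1

    def test_missing_age_matrix_names_age(self, guess_params):
        p = guess_params.copy()  # validated on construction; mutate afterwards
        del p.data["settings"]["rural"]["transitions"]["onset"]["13"]
        with pytest.raises(ConfigurationError, match="age 13"):
            m.run_cohort("rural", "digital", p)

    def test_trace_shape_and_cumulative_monotonicity(self, ref_params):
        from myopia_cea.cohort import TRACE_COLUMNS

        trace = m.run_cohort("urban", "traditional", ref_params)
        frame = trace.to_frame()
        assert list(frame.columns) == list(TRACE_COLUMNS)
        assert len(frame) == 13
        for col in ("cum_cost", "cum_qaly", "cum_daly"):
            assert (frame[col].diff().dropna() >= 0).all()
            assert (frame[col] >= 0).all()

    def test_prevalence_monotone_under_irreversibility(self, ref_params, guess_params):
        for params in (ref_params, guess_params):
            for setting in ("rural", "urban"):
                for name in m.STRATEGY_NAMES:
                    traj = m.prevalence_trajectory(m.run_cohort(setting, name, params))
                    assert (traj["total_myopia"].diff().dropna() >= -1e-12).all()
                    high = traj["p_high"]
                    assert (high.diff().dropna() >= -1e-12).all()

    def test_strategy_ordering_at_age_18(self, ref_params):
        """More education reach => weakly lower final prevalence."""
        prev = {}
        for name in m.STRATEGY_NAMES:
            trace = m.run_cohort("rural", name, ref_params)
            prev[name] = 1 - trace.occupancy[-1, 0]
        assert prev["digital"] <= prev["traditional"] <= prev["school_screening"]

    def test_surrogate_label_propagates_to_trace(self, ref_params):
        trace = m.run_cohort("rural", "digital", ref_params)
        assert "surrogate" in trace.label
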