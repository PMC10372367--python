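"""One-way analysis, PSA sampling and CEAC, percentile rules, subgroups."""

import numpy as np
import pytest

import myopia_cea as m
from myopia_cea.errors import ValidationError
from myopia_cea.params import ParameterSet
from myopia_cea.sensitivity import _sample_beta, _sample_gamma


@pytest.fixture(scope="module")
def bundle(ref_params):
    return m.ModelBundle(ref_params, "rural")


class TestPercentileInterval:
    def test_linear_interpolation_rule(self):
        lo, hi = m.percentile_interval(np.arange(1, 101))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_samples(self):
        assert m.percentile_interval([4.2] * 10) == (4.2, 4.2)

    def test_uniform_samples_near_analytic_quantiles(self):
        u = np.random.default_rng(7).uniform(size=1000)
        lo, hi = m.percentile_interval(u)
        assert lo == pytest.approx(0.025, abs=0.02)
        assert hi == pytest.approx(0.975, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            m.percentile_interval([])


class TestOneWay:
    def test_zero_fraction_reproduces_base(self, bundle):
        r = m.one_way("settings.rural.compliance.coverage", 0.0, bundle)
        assert r.low_ratio == pytest.approx(r.base_ratio, rel=1e-12)
        assert r.high_ratio == pytest.approx(r.base_ratio, rel=1e-12)

    def test_uninfluential_parameter_has_zero_range(self, bundle):
        """The screening test cost is identical across strategies and cancels
        out of every incremental ratio."""
        r = m.one_way("settings.rural.costs.screening_per_test", 0.20, bundle)
        assert r.width == pytest.approx(0.0, abs=1e-9)

    def test_coverage_bounds_match_two_independent_runs(self, bundle, ref_params):
        r = m.one_way("settings.rural.compliance.coverage", 0.10, bundle)
        for side, factor in (("low", 0.9), ("high", 1.1)):
            perturbed = ref_params.copy()
            base = perturbed.data["settings"]["rural"]["compliance"]["coverage"]
            # same clipping rule the one-way analysis applies to probabilities
            perturbed.data["settings"]["rural"]["compliance"]["coverage"] = min(
                base * factor, 1.0)
            ctx = perturbed.setting("rural")
            outs = [m.StrategyOutcome.from_trace(m.run_cohort(ctx, s, perturbed))
                    for s in m.STRATEGY_NAMES]
            expected = m.incremental_analysis(outs, ctx.gdp_per_capita).row("digital").ratio
            assert getattr(r, f"{side}_ratio") == pytest.approx(expected, rel=1e-12)

    def test_probability_bounds_are_clipped(self, bundle, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="myopia_cea.sensitivity"):
            r = m.one_way("settings.rural.compliance.coverage", 0.20, bundle)
        assert r.high_value <= 1.0
        if 0.918 * 1.2 > 1.0:
            assert any("clipped" in rec.message for rec in caplog.records)


class TestSamplers:
    def test_beta_moment_matching(self):
        rng = np.random.default_rng(0)
        draws = _sample_beta(rng, 0.3, 100.0, 200_000)
        assert draws.mean() == pytest.approx(0.3, abs=0.005)
        assert np.all((draws >= 0) & (draws <= 1))

    def test_structural_zero_and_one_stay_fixed(self):
        rng = np.random.default_rng(0)
        assert np.all(_sample_beta(rng, 0.0, 100.0, 10) == 0.0)
        assert np.all(_sample_beta(rng, 1.0, 100.0, 10) == 1.0)

    def test_gamma_moment_matching(self):
        rng = np.random.default_rng(0)
        draws = _sample_gamma(rng, 40.0, 0.2, 200_000)
        assert draws.mean() == pytest.approx(40.0, rel=0.01)
        assert draws.std() == pytest.approx(8.0, rel=0.05)
        assert np.all(draws >= 0)


class TestPSA:
    def test_degenerate_distributions_reproduce_base_case(self, bundle):
        res = m.run_psa(m.PSAConfig(iterations=4, seed=3, beta_ess=None, gamma_cv=0.0),
                        bundle)
        base = bundle.outcomes()
        for j, o in enumerate(base):
            assert res.costs[:, j] == pytest.approx(o.cost, abs=1e-9)
            assert res.qalys[:, j] == pytest.approx(o.qaly, abs=1e-9)
            assert res.dalys[:, j] == pytest.approx(o.daly, abs=1e-9)
        probs = res.ce_probability(30_501)
        assert set(probs.values()) <= {0.0, 1.0}

    def test_seed_determinism(self, bundle):
        a = m.run_psa(m.PSAConfig(iterations=200, seed=42), bundle)
        b = m.run_psa(m.PSAConfig(iterations=200, seed=42), bundle)
        c = m.run_psa(m.PSAConfig(iterations=200, seed=43), bundle)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert not np.array_equal(a.costs, c.costs)

    def test_ceac_probabilities_sum_to_one(self, bundle):
        res = m.run_psa(m.PSAConfig(iterations=500, seed=5), bundle)
        curve = res.ceac()
        probs = curve[[c for c in curve.columns if c.startswith("p_")]]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert len(curve) == 101
        assert curve["wtp"].iloc[-1] == pytest.approx(4 * 10_167)

    def test_low_dispersion_means_converge_to_base(self, bundle):
        res = m.run_psa(m.PSAConfig(iterations=2000, seed=11, beta_ess=1e6,
                                    gamma_cv=0.002), bundle)
        base = bundle.outcomes()
        for j, o in enumerate(base):
            assert res.costs[:, j].mean() == pytest.approx(o.cost, rel=0.01)
            assert res.qalys[:, j].mean() == pytest.approx(o.qaly, rel=0.001)

    def test_infinite_wtp_prefers_most_effective(self, bundle):
        res = m.run_psa(m.PSAConfig(iterations=50, seed=9, beta_ess=None, gamma_cv=0.0),
                        bundle)
        probs = res.ce_probability(1e12)
        assert probs["digital"] == 1.0

    def test_percentiles_bracket_base_case(self, bundle):
        res = m.run_psa(m.PSAConfig(iterations=2000, seed=21), bundle)
        pct = res.percentiles().set_index("strategy")
        for o in bundle.outcomes():
            assert pct.loc[o.name, "cost_p2.5"] < o.cost < pct.loc[o.name, "cost_p97.5"]
            assert pct.loc[o.name, "qaly_p2.5"] < o.qaly < pct.loc[o.name, "qaly_p97.5"]


class TestSubgroups:
    def test_chain_has_reference_plus_one_row_per_field(self, ref_params):
        table = m.subgroup_scenarios(ref_params, "rural")
        assert len(table) == len(m.SUBGROUP_FIELDS) + 1
        assert table["scenario"].iloc[0] == "traditional"

    def test_field_already_at_one_changes_nothing(self, ref_params):
        p = ref_params.copy()
        p.data["settings"]["rural"]["compliance"]["coverage"] = 1.0
        p = ParameterSet(p.data)
        table = m.subgroup_scenarios(p, "rural").set_index("scenario")
        outdoor = table.loc["perfect_outdoor_activity"]
        coverage = table.loc["perfect_vision_test_coverage"]
        assert coverage["cost_per_person"] == pytest.approx(outdoor["cost_per_person"],
                                                            abs=1e-9)
        assert coverage["incremental_cost_per_person"] == pytest.approx(0.0, abs=1e-9)
        assert coverage["incremental_daly_averted_per_person"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_outdoor_cost_anchor(self, ref_params):
        """Full outdoor coverage is the cheapest add-on scenario."""
        for setting, anchor in (("rural", 321.0), ("urban", 808.0)):
            table = m.subgroup_scenarios(ref_params, setting).set_index("scenario")
            model = table.loc["perfect_outdoor_activity", "cost_per_person"]
            assert model == pytest.approx(anchor, rel=0.01)
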