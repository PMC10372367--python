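"""Incremental analysis, dominance, ratios, WHO classification."""

import math

import numpy as np
import pytest

import myopia_cea as m
from myopia_cea.cea import CE, DOMINATED, HIGHLY_CE, NOT_CE
from myopia_cea.errors import ValidationError

RURAL_GDP, URBAN_GDP = 10_167, 13_856

# published per-person base-case values (cost USD, QALY, DALY)
RURAL = [("school_screening", 171, 9.57764, 0.06562),
         ("traditional", 218, 9.58509, 0.06189),
         ("digital", 324, 9.59448, 0.05905)]
URBAN = [("school_screening", 607, 9.56321, 0.06552),
         ("traditional", 729, 9.57119, 0.05886),
         ("digital", 819, 9.57964, 0.05670)]


def outcomes(rows):
    return [m.StrategyOutcome(n, c, q, d) for n, c, q, d in rows]


class TestComputeRatio:
    def test_plain_quotients(self):
        assert m.compute_ratio(4_700_000, 745) == pytest.approx(6308.72, abs=0.01)
        assert m.compute_ratio(100, 8) == 12.5
        assert m.compute_ratio(0, 5) == 0.0

    def test_zero_effect_gives_signed_infinity(self):
        assert m.compute_ratio(10.0, 0.0) == math.inf
        assert m.compute_ratio(-10.0, 0.0) == -math.inf
        assert m.compute_ratio(0.0, 0.0) == 0.0

    def test_sign_preserved_for_worsening_effect(self):
        assert m.compute_ratio(100.0, -5.0) == -20.0


class TestClassify:
    @pytest.mark.parametrize("ratio,gdp,expected", [
        (10_707, URBAN_GDP, HIGHLY_CE),
        (11_301, RURAL_GDP, CE),
        (37_446, RURAL_GDP, NOT_CE),
        (41_814, URBAN_GDP, NOT_CE),
        (-19_891, RURAL_GDP, DOMINATED),
    ])
    def test_who_rule(self, ratio, gdp, expected):
        assert m.classify(ratio, gdp) == expected

    def test_boundaries(self):
        assert m.classify(3 * RURAL_GDP, RURAL_GDP) == CE
        assert m.classify(3 * RURAL_GDP + 1, RURAL_GDP) == NOT_CE


class TestPublishedTableArithmetic:
    def test_rural_incremental_columns(self):
        _, _, combined = m.full_cea(outcomes(RURAL), RURAL_GDP)
        rows = combined.set_index("strategy")
        assert round(rows.loc["traditional", "incremental_cost_per_cohort"]) == 4_700_000
        assert round(rows.loc["digital", "incremental_cost_per_cohort"]) == 10_600_000
        assert round(rows.loc["traditional", "incremental_qaly_per_cohort"]) == 745
        assert round(rows.loc["digital", "incremental_qaly_per_cohort"]) == 939
        assert round(rows.loc["traditional", "incremental_daly_averted_per_cohort"]) == 373
        assert round(rows.loc["digital", "incremental_daly_averted_per_cohort"]) == 284
        assert round(rows.loc["traditional", "icur"]) == 6_309

    def test_urban_incremental_columns(self):
        _, _, combined = m.full_cea(outcomes(URBAN), URBAN_GDP)
        rows = combined.set_index("strategy")
        assert round(rows.loc["traditional", "incremental_cost_per_cohort"]) == 12_200_000
        assert round(rows.loc["digital", "incremental_cost_per_cohort"]) == 9_000_000
        assert round(rows.loc["traditional", "incremental_qaly_per_cohort"]) == 798
        assert round(rows.loc["digital", "incremental_qaly_per_cohort"]) == 845
        assert round(rows.loc["traditional", "incremental_daly_averted_per_cohort"]) == 666
        assert round(rows.loc["digital", "incremental_daly_averted_per_cohort"]) == 216

    def test_ratio_scale_invariance(self):
        per_person = m.compute_ratio(218 - 171, 9.58509 - 9.57764)
        per_cohort = m.compute_ratio((218 - 171) * 1e5, (9.58509 - 9.57764) * 1e5)
        assert per_person == pytest.approx(per_cohort, rel=1e-12)


class TestDominance:
    def test_needs_two_strategies(self):
        with pytest.raises(ValidationError):
            m.incremental_analysis([m.StrategyOutcome("only", 1, 1, 1)], 10_000)

    def test_duplicate_names_rejected(self):
        out = [m.StrategyOutcome("a", 1, 1, 1), m.StrategyOutcome("a", 2, 2, 2)]
        with pytest.raises(ValidationError, match="distinct"):
            m.incremental_analysis(out, 10_000)

    def test_identical_strategies_flag_duplicate(self):
        out = [m.StrategyOutcome("a", 100, 5, 1), m.StrategyOutcome("b", 100, 5, 1)]
        table = m.incremental_analysis(out, 10_000)
        flags = sorted(r.dominance for r in table.rows)
        assert flags == ["duplicate", "none"]

    def test_higher_cost_equal_effect_is_dominated(self):
        out = [m.StrategyOutcome("cheap", 100, 5, 1), m.StrategyOutcome("dear", 120, 5, 1)]
        table = m.incremental_analysis(out, 10_000)
        assert table.row("dear").dominance == "dominated"
        assert table.row("dear").ratio == math.inf

    def test_extended_dominance_textbook_case(self):
        # B's ICER vs A (1000/1=1000) exceeds C's ICER vs B (500/5=100) => B out
        out = [m.StrategyOutcome("A", 0, 0, 0),
               m.StrategyOutcome("B", 1000, 1, 0),
               m.StrategyOutcome("C", 1500, 6, 0)]
        table = m.incremental_analysis(out, 10_000, effect="qaly")
        assert table.row("B").dominance == "extended_dominated"
        assert table.frontier == ["A", "C"]
        # survivor C is compared with A, the previous non-dominated option
        assert table.row("C").comparator == "A"
        assert table.row("C").ratio == pytest.approx(1500 / 6)

    def test_frontier_icers_strictly_increase(self, rng):
        for _ in range(200):
            n = rng.integers(2, 7)
            out = [m.StrategyOutcome(f"s{i}", rng.uniform(0, 1000), rng.uniform(0, 10), 0)
                   for i in range(n)]
            table = m.incremental_analysis(out, 10_000)
            live = [r for r in table.rows if r.dominance == "none"]
            icers = [live[k].ratio for k in range(1, len(live))]
            assert all(b > a for a, b in zip(icers, icers[1:]))
            costs = [r.cost for r in live]
            effects = [r.effect for r in live]
            assert costs == sorted(costs)
            assert effects == sorted(effects)

    def test_frontier_matches_brute_force_mixture_oracle(self, rng):
        """Survivors = options not dominated by any convex mixture of two others."""

        def oracle_survivors(points):
            survivors = []
            for k, (ck, ek) in enumerate(points):
                dominated = False
                for i, (ci, ei) in enumerate(points):
                    if i != k and ci <= ck and ei >= ek and (ci < ck or ei > ek):
                        dominated = True
                    for j, (cj, ej) in enumerate(points):
                        if i == k or j == k or cj <= ci:
                            continue
                        if ci <= ck <= cj:
                            lam = (ck - ci) / (cj - ci)
                            mixed_effect = ei + lam * (ej - ei)
                            if mixed_effect > ek:
                                dominated = True
                if not dominated:
                    survivors.append(k)
            return survivors

        for _ in range(300):
            n = int(rng.integers(2, 7))
            points = [(float(rng.uniform(0, 100)), float(rng.uniform(0, 10)))
                      for _ in range(n)]
            out = [m.StrategyOutcome(f"s{i}", c, e, 0.0) for i, (c, e) in enumerate(points)]
            table = m.incremental_analysis(out, 10_000)
            expected = {f"s{i}" for i in oracle_survivors(points)}
            assert set(table.frontier) == expected, points
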