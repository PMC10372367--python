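"""Base-case cost-utility and cost-effectiveness analysis.

Runs the 13-cycle Markov cohort model (ages 6-18) for the three myopia
management strategies in both settings using the packaged calibrated
surrogate parameters, then prints per-person lifetime cost, QALYs and DALYs
and the incremental ratios against the previous strategy in cost order.
An ICUR below 1x per-capita GDP is highly cost-effective, below 3x
cost-effective, above 3x not cost-effective.
"""

import warnings

import myopia_cea as m

params = m.load_reference_parameters()
print(f"parameters: {params.label}  [{params.provenance}]")

for setting in params.setting_names:
    ctx = params.setting(setting)
    highly, ce = m.compute_thresholds(ctx.gdp_per_capita)
    print(f"\n{setting}: GDP per capita ${ctx.gdp_per_capita:,.0f} "
          f"(thresholds ${highly:,.0f} / ${ce:,.0f} per QALY or DALY)")
    outcomes = [m.StrategyOutcome.from_trace(m.run_cohort(ctx, s, params), ctx.cohort_size)
                for s in params.strategy_names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QALY/DALY frontiers may disagree
        _, _, table = m.full_cea(outcomes, ctx.gdp_per_capita)
    for _, row in table.iterrows():
        line = (f"  {row['strategy']:<18s} ${row['cost_per_person']:7.2f}  "
                f"{row['qaly_per_person']:.5f} QALY  {row['daly_per_person']:.5f} DALY")
        if row["comparator"]:
            line += (f"  | vs {row['comparator']}: ICUR ${row['icur']:,.0f} "
                     f"({row['icur_class']}), ICER ${row['icer']:,.0f} ({row['icer_class']})")
        print(line)
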