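"""Rebuild the surrogate parameter set from the published output targets.

Runs the full calibration pipeline — onset-curve scaling, education-exposure
and progression root finds, payoff and cost least squares — against the
packaged targets and prints the fit report.  The result should match the
shipped fixture (the pipeline is deterministic).
"""

import myopia_cea as m

params, report = m.calibrate()
print(report.to_text())

shipped = m.load_reference_parameters()
same = all(
    abs(m.run_cohort(s, strat, params).totals.cost
        - m.run_cohort(s, strat, shipped).totals.cost) < 1e-9
    for s in ("rural", "urban") for strat in m.STRATEGY_NAMES)
print(f"\nreproduces shipped fixture outputs: {same}")
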