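"""Probabilistic sensitivity analysis and acceptability curve.

Draws 10,000 parameter sets (beta distributions for probabilities,
compliances and weights; gamma for cost lines), re-runs the rural cohort
model per draw, and prints the probability that each strategy maximises net
monetary benefit at the WHO willingness-to-pay thresholds, plus 95%
uncertainty intervals of per-person outcomes.
"""

import myopia_cea as m

params = m.load_reference_parameters()
bundle = m.ModelBundle(params, "rural")
result = m.run_psa(m.PSAConfig(iterations=10_000, seed=7), bundle)

highly, ce = m.compute_thresholds(bundle.gdp_per_capita)
for label, tau in (("1x GDP", highly), ("3x GDP", ce)):
    probs = result.ce_probability(tau)
    txt = ", ".join(f"{s} {p:.1%}" for s, p in probs.items())
    print(f"P(most cost-effective) at {label} (${tau:,.0f}/QALY): {txt}")

print("\n95% uncertainty intervals (2.5th-97.5th percentile, per person):")
pct = result.percentiles().set_index("strategy")
for s in result.strategies:
    print(f"  {s:<18s} cost ${pct.loc[s, 'cost_p2.5']:.0f}-{pct.loc[s, 'cost_p97.5']:.0f}"
          f"  QALY {pct.loc[s, 'qaly_p2.5']:.4f}-{pct.loc[s, 'qaly_p97.5']:.4f}"
          f"  DALY {pct.loc[s, 'daly_p2.5']:.4f}-{pct.loc[s, 'daly_p97.5']:.4f}")

curve = result.ceac()
crossing = curve[curve["p_digital"] >= 0.5]["wtp"]
if len(crossing):
    print(f"\nCEAC: digital strategy preferred (p>=0.5) from about "
          f"${crossing.iloc[0]:,.0f} per QALY upward")
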