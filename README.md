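# myopia-cea

A Markov cohort cost-effectiveness model for school-age myopia prevention
and control strategies, written for health economists and epidemiologists
who want a transparent, scriptable alternative to spreadsheet or TreeAge
implementations of this class of decision model.

## The model

A closed cohort of 6-year-old schoolchildren is followed to age 18 in
annual cycles through four refractive states defined by cycloplegic
spherical equivalent (SE):

* non-myopia (SE > −0.5 D), low (−3.0 < SE ≤ −0.5), moderate
  (−6.0 < SE ≤ −3.0), high myopia (SE ≤ −6.0 D)

with forward-only progression `non → low → moderate → high` (myopia does
not regress). Three management strategies are compared in rural and urban
Chinese settings for a cohort of 100,000 children:

1. **school_screening** — semi-annual school vision tests (coverage 91.8%,
   non-cycloplegic, imperfect sensitivity/specificity), positives referred
   to hospital examination and treatment;
2. **traditional** — the screening cascade plus conventional health
   education promoting outdoor activity;
3. **digital** — the screening cascade plus digital health education
   (WeChat/SMS), reaching more students and parents.

Interventions act multiplicatively on transition probabilities with a
population-average reach: each modifiable probability *p* becomes
`p · (1 − reach · (1 − multiplier))`, where for cascade-delivered treatment
`reach = coverage · sensitivity · referral compliance · treatment
compliance` and for education-delivered outdoor activity
`reach = education exposure · outdoor compliance`.

Outcomes per person, discounted at 5%/year to age 6 over the 13 age points:

* cost (2021 USD, societal perspective: programme, examination, treatment,
  out-of-hospital direct and family time costs; 6.45 CNY/USD),
* QALYs (`Σ_age v^age Σ_state occupancy · utility`),
* DALYs (prevalence-based: `Σ_age v^age Σ_state occupancy · disability weight`).

Strategies are compared by ICUR (incremental cost per QALY gained) and ICER
(incremental cost per DALY averted) with strict and extended dominance, and
classified against the WHO willingness-to-pay benchmarks (1× and 3×
per-capita GDP: rural \$10,167 → \$30,501; urban \$13,856 → \$41,568).
Uncertainty is handled by one-way (tornado) analysis (±10%/±20%) and
probabilistic sensitivity analysis (beta/gamma resampling, 10,000 draws,
net-monetary-benefit acceptability curves, 2.5th/97.5th percentiles).

The original study's quantitative parameter appendix is not publicly
available, so the package ships a **calibrated surrogate parameter set**
(`myopia_cea/data/calibrated_params.json`, clearly labelled) fitted so the
model reproduces the published baseline prevalences, age-18 prevalences per
strategy, high-myopia reductions, and per-person cost/QALY/DALY magnitudes.
See `docs/methods.md` for the calibration design and its limits.

## Worked example

```python
import myopia_cea as m

params = m.load_reference_parameters()          # calibrated surrogate fixture
trace = m.run_cohort("rural", "digital", params)
print(f"age-18 myopia prevalence: {100 * (1 - trace.occupancy[-1, 0]):.2f}%")
print(f"per-person lifetime cost ${trace.totals.cost:.0f}, "
      f"QALYs {trace.totals.qaly:.5f}, DALYs {trace.totals.daly:.5f}")
```

prints

```
age-18 myopia prevalence: 85.37%
per-person lifetime cost $324, QALYs 9.60955, DALYs 0.05905
```

i.e. under the digital strategy 85.37% of the rural cohort is myopic at age
18 (versus 89.16% with screening alone — a 3.79 percentage-point
reduction), at a discounted lifetime cost of \$324 per child.

Longer narrative scripts live in `examples/`:

* `base_case_cea.py` — the base-case table with ICURs/ICERs and WHO
  classifications for both settings,
* `prevalence_trajectories.py` — prevalence paths from 6 to 18,
* `psa_and_ceac.py` — probabilistic sensitivity analysis and acceptability
  curve,
* `recalibrate_surrogate.py` — rebuild the surrogate fixture from the
  published targets and print the fit report.

A thin CLI wraps the same functions for shell use:

```sh
myopia-cea report                # consolidated base-case summary
myopia-cea cea --setting rural   # Table-shaped CSV/JSON
myopia-cea psa --setting rural --iterations 10000 --seed 7
```

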