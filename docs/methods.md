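# Methods

## Model structure

The core is a deterministic Markov cohort model: a closed cohort enters at
age 6 distributed over four refractive states (non, low, moderate, high
myopia by cycloplegic spherical equivalent at −0.5/−3/−6 D cut-offs) and is
pushed through one row-stochastic 4×4 transition matrix per year of age up
to 18 — 13 age points, 12 transitions. Two structural assumptions:

* **Irreversibility.** No transitions toward less myopic states; the HIGH
  state is absorbing. Consequence: total and high-myopia prevalence are
  monotone non-decreasing in age, and total prevalence at any age depends
  only on the onset path (useful for calibration, below).
* **Annual cycles, payoffs at every age point.** School vision tests occur
  every semester in practice; the model collapses them into one effective
  annual screening event with the published coverage (0.918), since
  per-semester parameters are not published. No half-cycle correction is
  applied (a config option, default off); with payoffs at all 13 age
  points the undiscounted full-health QALY total is exactly 13.

## Strategies and effect channels

All three strategies share the same non-cycloplegic screening test
(sensitivity 0.85, specificity 0.90 — surrogate values in the plausible
range for school vision tests). They differ in education channel, reach
and follow-up compliance:

* outdoor activity is education-delivered: its reach,
  `education_exposure × outdoor_compliance`, does not require a positive
  screen, because health education targets all students;
* optical/clinical treatment is cascade-delivered: reach is
  `coverage × sensitivity × referral_compliance × treatment_compliance`.

Each modifiable transition probability p becomes
`p (1 − reach (1 − multiplier))` — the population-average of treated
children (probability scaled by the multiplier) and untreated children.
The diagonal absorbs the difference, keeping rows stochastic.

The screening-only strategy carries its own, lower referral compliance
(calibrated): without an education channel feeding results back to schools
and parents, follow-up after a positive screen is weaker. The education
strategies use the published base-case compliances (hospital examination
0.353 rural / 0.733 urban; spectacles 0.36 / 0.683; outdoor 0.838).

False positives (non-myopic children failing specificity) incur one
hospital-examination cost — including the out-of-hospital direct costs and
family time loss bundled into that cost line — but no effect change,
consistent with a societal-cost perspective.

## Economics

Costs are 2021 USD (6.45 CNY/USD; older prices brought forward at
5%/year). Cost, QALYs and DALYs accrue at each age point and are
discounted to age 6 at 5%/year by default (configurable, including 0). The
5% default matches the study's cost-adjustment rate and the magnitude of
its printed cumulative QALYs (≈9.58 against a 13-point annuity factor of
9.8632 at 5%). DALYs are prevalence-based years lived with disability
(occupancy × disability weight per year); there is no mortality in the
model and hence no years-of-life-lost term. Per-100,000 outcomes are exact
multiples of per-person outcomes (the model is linear in cohort size;
cohort size 0 is allowed, per-person outputs remain defined).

Incremental analysis sorts strategies by cost, removes strictly dominated
options, then iteratively removes extendedly dominated ones (sequential
ICER exceeding the next option's); survivors form a frontier with strictly
increasing costs, effects and ICERs, verified in tests against brute-force
enumeration of two-strategy convex mixtures. Because published practice in
this literature reports "each strategy versus the previous one in cost
order" even when extended dominance fires, the combined base-case table
reports those sequential ratios with the rigorous dominance flags
alongside; the QALY- and DALY-coordinate analyses are both run, with a
warning when their frontiers disagree. Ratios are kept at full precision;
rounding to whole dollars happens only in the human-readable report.

## Uncertainty analysis

* **One-way:** a scalar is re-set to base × (1 ± f), f = 10% for
  probabilities and 20% for cost lines by default (configurable); the full
  deterministic pipeline is re-run at each bound. Probabilities leaving
  [0, 1] are clipped with a logged warning.
* **Probabilistic:** beta distributions for probabilities, compliances,
  test characteristics, utility *decrements* and disability weights
  (moment-matched: α = m·n, β = (1−m)·n with effective sample size n = 100
  by default), gamma distributions for cost lines (coefficient of
  variation 0.2, shape 1/cv²). Structural 0/1 values are constants, not
  uncertain quantities, and stay fixed. All strategies share each draw, so
  common parameters stay correlated across strategies; baseline state
  prevalences are treated as data and are not resampled. The dispersion
  defaults are conventional health-economics PSA practice; the published
  analysis states the distribution families but not their variances.
* **CEAC:** probability of maximising net monetary benefit
  (effect × willingness-to-pay − cost) over a grid of 101 points from 0 to
  4× per-capita GDP. Percentile intervals use linear interpolation between
  order statistics (quantile "type 7").
* **Subgroups:** cumulative perfect-compliance variants of the digital
  strategy in the order outdoor activity → vision-test coverage →
  spectacles → hospital examination, each compared with the previous row.

The PSA engine is vectorised over draws; a test pins it to the scalar
cohort engine by requiring degenerate (zero-variance) distributions to
reproduce the base case to 1e−9.

## Surrogate calibration

The study's parameter appendix (age-specific transition probabilities,
effect sizes, weights, cost lines) is not publicly deposited. The
calibration module therefore constructs a surrogate parameter set — every
artifact derived from it carries the label *"calibrated surrogate, not
original appendix values"* — fitted to the published outputs only. No
claim is made that the fitted parameters recover the original appendix
values; with ~20 printed targets the problem is under-determined, which is
why the parameterisation is deliberately low-dimensional:

1. **Onset curve.** Annual onset is a piecewise-linear age curve over knots
   at ages 6/10/14/17 (shape 0.6/1.2/1.0/0.6: onset rises through primary
   school, peaks in early adolescence, tapers). Because total prevalence
   depends only on the onset path, the curve's scale is root-found
   (Brent) against the screening-strategy age-18 prevalence, and the
   education strategies' onset-reduction factors against their age-18
   prevalences; education exposures follow in closed form from the outdoor
   compliance and multiplier. These prevalence targets are matched
   essentially exactly.
2. **Progression.** The moderate→high level is root-found against the
   published high-myopia reduction (digital vs screening). Three remaining
   structural scalars per setting — the low→moderate level, the
   screening-only referral compliance, and the setting's treatment
   progression multiplier — are searched by Nelder–Mead against the
   QALY/DALY/cost anchors. The per-setting treatment multiplier reflects
   different treatment portfolios and follow-up quality between settings.
3. **Payoffs.** Utility decrements and disability weights enter the
   discounted totals linearly, so they are fitted by non-negative least
   squares with severity-ordering constraints (w_low ≤ w_mod ≤ w_high via
   an increment reparameterisation). Weights are *per setting*: the
   effective annual weight of a myopic state is a mixture of corrected and
   uncorrected vision-impairment weights, and access to correction differs
   between rural and urban children. Strategy-to-strategy increments are
   fitted alongside the levels because they feed the ICUR/ICER numerators
   and denominators.
4. **Costs.** Cost lines (education traditional/digital, hospital
   examination, annual treatment) multiply discounted utilization
   quantities linearly and are fitted by weighted non-negative least
   squares against the base-case and perfect-compliance cost anchors, with
   the screening test cost held at a realistic fixed value (≈CNY 10 per
   test). The digital→perfect-outdoor cost increment is excluded from the
   increment rows: its printed value (−\$11 urban) is incompatible with
   the level anchors under any non-negative utilization costing, so the
   level anchors arbitrate (both end within 1%).

The shipped fixture converges on every hard target: baseline prevalences
exact by construction, age-18 prevalences and high-myopia reductions
within 0.05 percentage points (in practice <1e−6), and all base-case and
perfect-outdoor cost, QALY and DALY anchors within 1% relative. The fit
report (`myopia_cea/data/fit_report.json`) lists every target with its
deviation; non-convergence would be reported explicitly, never silently
accepted. Remaining soft deviations are documented there: the later
perfect-compliance chain costs (within ~2–20%), and the published DALY
*increases* under perfect vision-test coverage (rural) and perfect
hospital examination (urban), which are structurally impossible in a model
where more screening and treatment weakly improve outcomes.

Published ICURs/ICERs were evidently computed from unrounded per-person
values; only the rural traditional ICUR (4,700,000/745 → 6,309) is exactly
recoverable from printed inputs. The fixture's recomputed ratios land
close (e.g. rural traditional ICUR ≈ 6,196, rural digital ICER ≈ 37,309
against printed 37,446) but are not forced to printed values.

## Numerical choices and degenerate inputs

* Occupancy conservation is enforced at 1e−9; the cohort engine matches an
  independent step-by-step matrix-multiply oracle at 1e−12.
* Ratio of zero incremental effect returns a signed-infinity sentinel and a
  dominance flag rather than raising.
* Equal-cost ties: lower effect is dominated; equal cost and effect is
  flagged `duplicate` with stable order.
* Root finds use Brent's method with brackets checked first; an unreachable
  target raises a calibration error naming the setting and target.
* Parameter files are validated eagerly on load; errors name the block,
  age and matrix row concerned. Probabilities are fractions in files;
  percents appear only in reports.

## Problem sizes

The deterministic pipeline is tiny (13 cycles × 4 states); a full
calibration takes a few seconds and the 10,000-draw PSA under a second
(vectorised), so all defaults are run as published: 10,000 Monte-Carlo
draws, 101-point CEAC grid, 100,000-person cohort scaling.

## Known limitations

* The surrogate is identified at the *output* level only; many parameter
  sets reproduce the same printed outputs, and the fitted values (e.g. the
  strong urban treatment multiplier, the zero traditional-education cost
  line) should not be read as empirical estimates.
* The generator emulates the study's printed conditions, not real
  longitudinal refraction data: no between-child heterogeneity, no
  per-semester screening dynamics, no natural-environment covariates, no
  regression toward emmetropia. Passing tests show the decision-analytic
  machinery is correct under these conditions, not that the surrogate
  parameters describe any real cohort.
* No mortality, no adult outcomes, no pathological-myopia complications,
  no other paediatric eye diseases; costs and benefits stop at age 18.
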