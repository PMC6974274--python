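# Methods

## The decision problem

Annual microalbuminuria screening in diabetic patients can be done with the
quantitative laboratory uACR assay (accurate, expensive, needs two trips —
sample drop-off and result visit) or a semi-quantitative point-of-care strip
(cheap, immediate, but imperfect). A strip-based programme trades test cost
against the downstream cost of albuminuric patients the strip misses, whose
risk of ESRD, CVD and death is elevated. The package quantifies that
trade-off per screened person over a ten-year horizon.

## Diagnostic accuracy

Concordance tables cross-tabulate quantitative category (rows) against
semi-quantitative category (columns) over the bins <30, 30–300 and ≥300 mg/g;
both edges belong to the upper bin, so 30 mg/g is positive. All screening
metrics are dichotomised at 30 mg/g:

- sensitivity = concordant positives / quantitative positives,
- specificity = concordant negatives / quantitative negatives,
- over-detected = false positives / all screened,
- under-detected = false negatives / all screened,
- NNS = 1/sensitivity.

NNS here is the expected number of test applications per true case detected.
That definition is an inference: it reproduces all six published NNS values
(1.1, 1.2, 1.1, 1.2 for the strip and 1.5, 1.9 for the dipstick) at
one-decimal rounding, and the test suite pins exactly that. Dipstick-vs-
quantitative comparisons are ordinary dichotomised tables (positives placed
in the 30–300 bin; only the 2×2 margins matter), not a separate code path.

The published dipstick false-positive fractions are printed per 100 without a
stated denominator; the package computes FP/n (all screened), the same
convention as the over-detected fraction. The alternative FP/negatives
denominator would give larger values.

## Screening-tree proportions

Four proportions drive the cycle tree, each carried as beta pseudo-counts
from its source table (development subgroup, n = 1,110):

| proportion | counts | mean |
|---|---|---|
| negative at quantitative screen | Beta(917, 193) | 0.826 |
| negative at strip screen | Beta(615, 495) | 0.554 |
| false negative among strip negatives | Beta(36, 579) | 0.0585 |
| true positive among strip positives | Beta(157, 338) | 0.317 |

The deterministic engine uses the full-precision means; the counts are kept
for provenance and for future probabilistic sensitivity analysis. The
validation parameterisation rebuilds the same four proportions from the
external cohort's subgroup counts (n = 301: TN 187, FP 68, FN 8, TP 38).

## Markov cohort model

One-year cycles, ten cycles, cohort mass 1 at entry. Per cycle, in order:

1. every occupant is screened (screen count += occupancy);
2. quantitative arm: the positive fraction exits to medical care.
   Strip arm: the positive fraction receives a confirmatory quantitative
   test; confirmed true positives exit, confirmed false positives stay;
3. outcome probabilities apply to the remaining strata. Rates convert to
   probabilities by the constant-hazard formula p = 1 − e^(−rate·time);
   albuminuric (false-negative) occupants use rate·HR in the exponent.
   The three outcomes are converted independently and treated as mutually
   exclusive within a cycle — their probability sum is removed from
   occupancy. A renormalised competing-risk allocation would be defensible
   but does not reproduce the published cost rows; with annual probabilities
   of ~0.6–2%, the difference is third-order;
4. survivors re-enter the node memorylessly: screening results are re-drawn
   each cycle from the same proportions, with no persistence of a patient's
   false-negative status. Events and exits are absorbing, including CVD
   (no survivor re-entry) — the tree offers no re-entry path for them.

No half-cycle correction is applied; screening happens at cycle start and
events within the cycle.

## Baseline inputs

Costs in 2016 USD (1 USD = 1,160 KRW). Unit costs: quantitative test 17.76,
strip test 0.86, transportation 9.265 per trip. Outcome parameters:

| outcome | annual rate (normo-albuminuric) | HR (95% CI) | unit cost |
|---|---|---|---|
| ESRD | 0.0006 | 3.432 (2.757–4.271) | 6,810.38 |
| CVD | 0.0154 | 1.315 (1.250–1.384) | 13,149.62 |
| death | 0.0095 | 1.480 (1.408–1.556) | 25,634.48 |

Two provenance notes. First, the source material's parameter table and its
narrative disagree on which rate/cost pairs with which outcome; the
assignment above follows the narrative, which is the only assignment that
reproduces the published per-outcome cost rows, and treats the table's row
labels as permuted. Second, the model HRs above differ slightly from the
pooled HRs the same source reports from its own meta-analysis (3.27, 1.31,
1.48); the model consumes the table values, which again reproduce the
published cost rows. Both discrepancies are inherited from the source and
surfaced here rather than resolved. The death "cost" is a willingness-to-pay
value of one life-year and is discounted like every other cash flow.

Transport multiplicity is two trips per quantitative screen, one per strip
screen and one per confirmatory test. These integers are reverse-engineered:
each published transport row divided by the trip cost equals the
corresponding test count times exactly 2, 1 and 1, and the defaults are
exposed as configuration (`transport_trips_*`).

## Cost accounting

Per cycle t (t = 0 first), each component's cash flow is the relevant count
times its unit cost; discounted flows multiply by (1.03)^(−t), so the first
cycle is undiscounted — the convention that matches the published discounted
totals. Outcome costs are one-off per event with no multi-year tail, and
accrue only in the screen-negative ("unavoided") strata: quantitative
negatives, strip true negatives and strip false negatives. Events among
confirmed false positives are recorded by the engine but not costed — they
are known normo-albuminuric patients, so their events are not attributable
to a screening error; `cost_breakdown(include_false_positive_events=True)`
flips that convention. Exits to medical care carry no downstream cost, so
the analysis is a cost comparison of screening programmes, not a
cost-effectiveness analysis (no QALYs, no ICER).

The saving is quantitative-total minus strip-total, reported crude and
discounted, absolute and as a fraction of the quantitative total.

## Meta-analysis

Study effects enter as HR with a 95% CI; the log-scale standard error is
(ln CI_high − ln CI_low)/(2z) with z = 1.959964 (full-precision normal
quantile — rounding to 1.96 shifts back-transformed SEs in the fourth
decimal). Fixed effects are inverse-variance weighted; the random-effects
between-study variance is the DerSimonian–Laird moment estimator
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), with final weights 1/(se² + τ²).
Heterogeneity is reported as Q, I² and the upper-tail χ²(k−1) p-value.
A single study passes through unchanged with τ² = I² = 0. No REML or
Paule–Mandel variants, no publication-bias diagnostics, no meta-regression.
The bundled study set is illustrative (synthetic, in plausible ranges); the
tests validate pooling on properties, an independent statsmodels
implementation, and parameter-recovery simulations, not against any
published forest plot, whose per-study inputs are not available as data.

## One-way sensitivity (tornado)

Each scalar parameter is set to its low and high bound with everything else
at baseline, both strategies re-run, and the saving recomputed. Default
ranges: unit costs and incidence rates ±20%, hazard ratios across their 95%
CIs. The default basis is the discounted saving (baseline 414.89 USD), whose
published range for the cost-of-death bar (375.6–454.1) brackets it
symmetrically; crude is selectable. Entries are ordered by span, widest
first. Savings are exactly linear in every unit cost given a fixed trace,
which the tests verify through the two-point midpoint identity.

## Synthetic data and micro-simulation

`generate_cohort` draws true categories from a 3-class prior (default: the
development subgroup prevalence 82.6/16.8/0.6%) and observed strip categories
from a row-stochastic confusion matrix (default: the development subgroup's
row-normalised table). Continuous uACR values are log-uniform within the true
bin (upper bin capped at 3,000 mg/g); they only matter through their bin, so
the draw is cosmetic but keeps records realistic. The generator does not
model longitudinal uACR trajectories, treatment effects, assay drift, or
correlated test errors across cycles — so passing recovery tests show the
estimators are consistent under the stated data-generating process, not that
real screening data meet that process.

`generate_meta_studies` draws study log-HRs from Normal(θ, τ² + se²) with
per-study se uniform in a range (default 0.05–0.30, typical of cohort-study
HRs), CIs back-computed at 95%.

`microsimulate` walks individual patients through the identical tree with
Bernoulli/categorical draws and identical cost conventions. It is the
independent check of the cohort engine: at n = 10⁵ every cohort expectation
(screens, confirmatory tests, per-outcome event fractions, crude and
discounted mean costs) must sit within 3 Monte-Carlo standard errors, and
does. All generators are pure functions of (parameters, seed) using numpy's
PCG64 generator.

## Numerical and testing choices

- Mass conservation (occupancy = exits + events + survivors) is asserted to
  10⁻¹²; the cost decomposition to 10⁻⁹.
- Published-table reproductions are tested at ±1% (the source appears to have
  used 3-decimal rounded proportions, worth ≤0.1%); the tornado bounds at
  ±2%; accuracy metrics are exact integer arithmetic and tested at printed
  precision.
- DL coverage is tested on 500 replicates of k = 30 studies with τ = 0.2
  against a 0.92–0.98 band: nominal 95% minus DL's known mild undercoverage,
  plus three binomial standard errors (±0.03) of Monte-Carlo noise.
  Problem sizes (n = 10⁵ cohorts, 500 meta replicates) keep the full
  stochastic suite under a few seconds while leaving standard errors small
  enough for 3-SE assertions to be meaningful.
- Degenerate inputs fail loudly: empty record sets, zero denominators
  (sensitivity with no positives, NNS at zero sensitivity), inverted CIs,
  mixed-outcome pooling, combined per-cycle probabilities above 1, and
  unknown sensitivity-parameter names all raise with the offending item
  named.

## Known limitations

- The cohort is memoryless: a false negative this year is redrawn next year,
  so persistent assay-specific blind spots (e.g. a patient whose uACR always
  reads low on the strip) are not representable.
- Treatment after a positive screen is an absorbing exit with no modelled
  cost or benefit; the model compares screening programmes, not care
  pathways.
- Outcome costs are one-off event costs; chronic post-event costs (dialysis
  years, post-stroke care) are out of scope.
- National-scale budget extrapolations are out of scope: per-person savings
  times any plausible diabetic population cannot be reconciled with the
  source's nationwide claim, so the package does not attempt one.
- The probabilistic machinery (beta counts) is carried but unused by the
  deterministic engine; a full probabilistic sensitivity analysis with
  acceptability curves is future work.
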