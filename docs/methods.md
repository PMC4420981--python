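# Methods

This note records the modelling choices behind `dietshift`: the two-stage
model, the defaults and their units, what the synthetic inputs do and do
not emulate, and the numerical conventions.

## 1. Diet optimisation

The optimiser treats the population-average diet of each sex as a vector
of food-group intakes (g/day) and finds the feasible diet closest to the
baseline in welfare-weighted squared-percentage terms.

**Weights.** Willingness to change a food group is proxied by consumer
behaviour: a group with a large expenditure share *s* and a small
own-price elasticity |*e*| is one people hold on to, so deviations there
are penalised more. The default weight is `w = s/|e|`, normalised to mean
one. The functional form is a package choice — the welfare argument fixes
only the monotonicities — and alternative weights can be passed directly
to `optimise_diet`.

**Constraints.** All are linear in the intake vector:

* nutrient bounds, either absolute (fibre ≥ 25 g/day, sodium ≤ 2 g/day)
  or as a share of dietary energy (total fat ≤ 30%, saturated fat ≤ 10%,
  free sugars ≤ 10%, converted with Atwater factors of 9 and 4 kcal/g).
  Because total energy is held at its baseline value, percent-of-energy
  bounds reduce to linear bounds on nutrient energy;
* combined fruit + vegetable mass ≥ 400 g/day;
* total energy equal to baseline (the scenarios are about composition,
  not quantity);
* the liquid share of diet mass equal to baseline. Mass was chosen as
  the measure because it is well defined for every group without extra
  data; the flag lives on the food table, the equality in the constraint
  set;
* optionally, dietary emissions ≤ (1 − r) × baseline for a target
  reduction r. This is an inequality, not an equality: at loose targets
  the nutrition constraints alone already cut emissions, so the achieved
  reduction can exceed the target and is always reported;
* non-negativity; groups may be driven to zero (processed meat is, at
  tight targets).

The default bound values are shipped as an editable YAML
(`data/who_constraints.yaml`); they follow widely used population intake
goals but are configuration, not a claim about any particular guideline
edition.

**Solver.** The objective is a diagonal positive-definite quadratic and
the constraints are linear, so the problem is a convex QP with a unique
optimum on a non-degenerate feasible set. It is solved in units of the
baseline diet (`u = x/c`, which conditions the Hessian) by scipy's
`trust-constr` with analytic gradient and Hessian; constraint rows are
rescaled to order one using the baseline magnitude of each constrained
quantity. Eight starts (baseline plus seven seeded perturbations) are
run; convexity makes them redundant, and the test suite uses their
agreement as a solver diagnostic. Feasibility is accepted at a relative
tolerance of 1e-6 per constraint. If no feasible point is found, a
penalty minimisation locates the least-violated point and the error names
the worst constraint; partial answers are never returned.

## 2. From diets to hazards

Exposure changes are the summed g/day differences over the groups tagged
fruit, vegetable, red meat and processed meat. Each exposure–disease
pathway carries a relative risk per reference increment (e.g. 0.93 per
80 g/day of fruit for coronary heart disease) and scales log-linearly:
`RR^(Δ/increment)`. Pathways with mixed reference increments are kept
per-row; nothing is renormalised to a common increment. Where several
exposures affect one disease the scaled risks multiply. Central risks are
used in the main analysis even where a pathway's confidence interval
spans one; the interval matters only in sensitivity runs, where "low
impact" takes the bound nearest one for every pathway (weakening
protective and harmful effects alike) and "high impact" the far bound.
No truncation is applied to extrapolations beyond the reference
increment; at the deltas the optimiser produces (≤ ~2 increments) the
log-linear form stays in a plausible range.

## 3. Time lags

The fraction of a hazard change realised *t* years after adoption is a
normal CDF rescaled so that it is exactly 0 at the onset delay and
exactly 1 at the full-effect time:

| class | onset | full effect | CDF location | CDF scale |
| --- | --- | --- | --- | --- |
| cardiometabolic (CHD, stroke, type 2 diabetes) | 0 y | 10 y | 5 y | 2 y |
| cancer (oral, oesophageal, lung, stomach, colorectal) | 10 y | 30 y | 20 y | 3.3 y |

The location/scale values are package defaults chosen to satisfy the
boundary conditions with a symmetric rise over the active interval; they
are fields on `LagFunction` and can be replaced per analysis. The lag
interpolates multipliers on the rate scale, `M(t) = 1 + f(t)(RR − 1)`;
the geometric alternative `RR^f(t)` differs only in the third decimal for
risks of this size.

## 4. Life-table projection

The engine follows the standard impact-assessment life-table design:
discrete annual steps, within-year exponential survival at the annual
rate, person-years by the half-interval (trapezoid) convention, ages 0 to
100 with the terminal age absorbing and its rate closing the table.
Scenario hazards modify only the cause-specific components:
`m'(a,t) = m(a) + Σ_d m_d(a)(M_d(t) − 1)`, lag weights evaluated at
mid-year. Negative modified hazards are clipped at zero with a logged
warning (unreachable for multipliers ≥ 0 when cause rates sum below the
all-cause rate, but guarded anyway).

* **YLL averted** uses the current closed population — no future births,
  underlying rates constant — projected under baseline and scenario
  hazards; the cumulative person-year difference is reported at 20- and
  30-year horizons. Per-disease figures switch on one disease's
  multiplier at a time; their sum is close to, but not exactly, the
  joint-scenario total (interactions are sub-5% on the default fixture),
  and the joint total is the headline number.
* **Life expectancy at birth** follows a birth cohort whose age equals
  time since adoption, so lags phase in along its life; the change is
  scenario minus baseline cohort expectation, in months. The open-ended
  interval beyond the last age contributes `l/m` (exact for constant
  hazard).

`life_expectancy` accepts a sub-year step for convergence studies; with a
constant hazard its error against `1/m` shrinks quadratically in the
step.

## 5. Synthetic inputs

The generators produce, from one integer seed, everything the pipeline
consumes. They emulate the *structure* of the real national datasets, not
their values:

* **Food groups** — 42 groups per sex assembled from 13 category
  templates (fruit, vegetables, red and processed meat, cereals, milk,
  dairy, fish, eggs, snacks, soft and hot drinks, other), with lognormal
  jitter on composition and intensity, Dirichlet-style splits of category
  totals, elasticities in (−1.3, −0.25) and price-weighted expenditure
  shares. Category totals put baseline fruit near 140 g/day, energy at
  2300–2900 kcal/day and dietary emissions at 4–5.5 kgCO₂e/day, and the
  baseline mildly violates the default constraints in the directions
  typical of a Western diet (saturated fat, free sugars and sodium high;
  fibre and fruit + vegetables low) so the optimiser has realistic work
  to do. GHG intensities were chosen from published life-cycle ranges
  (meat ≫ dairy > fruit > vegetables ≈ cereals); with these values the
  nutrient-feasible emissions floor sits below a 60% reduction for both
  sexes, so the full target ladder is attainable, as in the study design
  the package follows.
* **Population** — Gompertz–Makeham all-cause mortality per sex with an
  infant excess, terminal rate 1 at age 100, stationary age structure of
  400 k births/sex/year (±5% noise), and cause-specific rates as
  logistic age-ramped fractions of all-cause mortality — which makes the
  Σ cause ≤ all-cause invariant true by construction. Implied life
  expectancies are in the high-70s/low-80s.
* **Exposure–response** — the packaged 17-pathway literature table
  (verbatim fixture, `data/table1_erfs.csv`), or the same structure with
  randomised risks for stress tests.

What passing tests on these fixtures shows is that the *method* behaves
correctly — monotone trade-offs, exact null results, solver–oracle
agreement, ordered sensitivity brackets. It does not validate the
magnitudes against any real population: headline numbers from the
synthetic fixture (e.g. ~6.8 M YLL averted over 30 years with no GHG
target at seed 1) are properties of the fixture, not UK estimates.

## 6. Aggregation and reporting conventions

Sexes are optimised independently (their baselines and constraints
differ); population GHG reductions are the equal-weight mean of the sexes
unless weights are supplied, and population YLL is the sum. The sweep
records a failed target (infeasible or non-converged) as an explicit
error row rather than dropping it. The deviation index reported per
target is the optimiser objective at the solution — on the default
fixture it stays within a factor of ~3 of the nutrition-only value up to
a 50% reduction and then jumps by an order of magnitude at 60%, which is
the acceptability cliff the index exists to expose. No acceptability
threshold is hard-coded.

## 7. Problem sizes and determinism

Default analyses use 42 food groups × 2 sexes, ages 0–100, horizons of
20 and 30 years; a full seven-target sweep solves 14 QPs and ~130
life-table projections in about a minute on one CPU. All randomness
(synthetic generation, solver starts) derives from user-supplied integer
seeds; repeated runs are bit-identical.

## 8. Known limitations

* Mortality only; morbidity benefits are out of scope, so totals
  understate health gains.
* Baseline mortality is frozen at its current schedule; secular declines
  in cardiovascular mortality would shrink absolute YLL numbers.
* Price elasticity and expenditure share enter only through the scalar
  deviation weights; there is no demand-system or substitution model.
* The log-linear exposure–response form is extrapolated beyond reference
  increments without truncation.
* Per-disease YLL attribution by one-at-a-time switching ignores
  (small) interaction terms.
* Population-average diets only; distributional questions (age- or
  income-specific diets) are not addressed.
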