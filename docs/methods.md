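# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite can show. All notation:
groups are `pub` (public model of care) and `pri` (private); outcomes are
binary indicators for elective (ELCS) and emergency (EMCS) caesarean
section; `F` is the link's response function (standard-normal CDF for the
default probit).

## Outcome models

Each outcome is modelled as `P(Y=1|X) = F(Xβ)` and estimated by maximum
likelihood (Newton, gradient tolerance 1e-8, at most 100 iterations;
delegated to statsmodels). The identity link is the linear probability
model fit by OLS; it exists chiefly because the decomposition has an exact
closed form there, which anchors the tests. Its pseudo-R² uses the
Bernoulli log-likelihood with probabilities clipped to `[1e-10, 1-1e-10]`.

* **Robust covariance** is the Huber–White sandwich (HC1), the "robust
  standard errors" convention of the applied literature.
* **Average marginal effects.** Binary/dummy columns use the average
  discrete change `mean[F(X|x_k=1) − F(X|x_k=0)]`; continuous columns use
  the average density-weighted slope `mean[f(Xβ)]·β_k`. Column kind is
  declared by the design builder, never inferred from values at AME time.
  Standard errors are delta-method against the robust covariance; the
  implementation is cross-checked against `statsmodels.get_margeff` in the
  test suite. Toggling a dummy does not zero its categorical siblings; for
  the rare rows where two dummy levels of one family would both be 1 under
  the counterfactual this slightly departs from factor-variable semantics,
  and contributions in the decomposition (which switch whole observed
  vectors) are unaffected.
* **Pseudo-R²** is McFadden's `1 − ll(model)/ll(intercept-only)`.
* **Estimation-sample convention.** The elective model excludes emergency
  deliveries from its estimation sample and vice versa
  (`exclude_if_positive`), matching the usual denominator convention when
  the two outcomes are modelled separately; this is configurable. Listwise
  deletion removes rows missing any model variable.
* **Separation.** A binary column that perfectly partitions the outcome is
  detected before optimisation and reported by name. *Quasi*-separation —
  a rare indicator (e.g. pre-existing diabetes at 0.2–0.3% prevalence)
  whose few carriers all share one outcome — leaves the likelihood without
  an interior maximum; Newton then oscillates and the fit falls back to
  L-BFGS, which settles on the likelihood plateau (the offending
  coefficient around ±5, predictions at the boundary). The fit is accepted
  only if the score has genuinely vanished (max |score| < 1e-4·n),
  otherwise estimation fails loudly. This mirrors what Stata achieves by
  dropping the predictor and its observations, while keeping the design
  identical across the reference fits the decomposition compares.
* **Rank deficiency** is detected via QR with column pivoting and reported
  as the list of collinear columns.

## The decomposition

Aggregate: `explained = mean F(X_pub β̂*) − mean F(X_pri β̂*)` over the
two-group analysis sample, `unexplained = gap − explained` (exact).
Reference coefficients `β̂*` come from the public fit, the private fit, or
a pooled fit. The pooled fit excludes the group dummy by default; with
`pooled_includes_group_dummy=True` the dummy is estimated but its
coefficient is zeroed when evaluating decomposition predictions, so the
counterfactuals never price group membership itself. Both conventions
appear in the literature and the choice is reported in the output header.

Detailed contributions (Fairlie procedure), per replication:

1. the larger group is subsampled without replacement to the smaller
   group's size (at the default calibration, public → 7,811);
2. observations are paired across groups by the rank of their predicted
   probabilities under `β̂*`; ties are broken by a seeded uniform
   perturbation of magnitude 1e-12 before sorting — deterministic given
   the replication's RNG substream, unbiased across ties;
3. covariate blocks are switched from public to private values in a fresh
   uniform random order; block `k`'s contribution is the change in mean
   predicted probability at its step. The steps telescope exactly to the
   matched sample's explained gap.

Contributions are averaged over replications (default 1,000; each
replication runs on an independent RNG substream keyed by its index, so
results are invariant to execution order). The default block structure is
one block per design column, so each dummy level of a categorical family
is listed separately; `covariate_blocks` switches whole families jointly.
A `(residual)` row holds the aggregate explained term minus the summed
contributions — pure Monte-Carlo subsampling error, identically ~0 when
the groups are equal-sized and shrinking in R otherwise.

**Standard errors.** Default: the empirical standard deviation of
per-replication contributions divided by √R — the Monte-Carlo error of the
reported average, transparent and directly testable. A delta-method
variant (`se_method="delta"`), propagating the reference fit's robust
covariance through the averaged contribution gradients, is available; it
reflects sampling error in `β̂` instead and is typically much larger. The
two estimate different uncertainties and no equivalence with Stata's
output is claimed.

**Signs.** The gap is `Ȳ_pub − Ȳ_pri` (negative when the private rate is
higher). The `% of gap` column is `contribution / gap × 100`, so a
contribution that widens the negative gap prints as a negative
percentage-point value with a positive share.

Failed replications (degenerate subsamples) are skipped and counted; more
than 1% failures aborts the run.

## Synthetic cohort

The generator emulates the structure the analysis needs: two groups of
unequal size with group-specific covariate mixes and index-model outcomes.
Defaults calibrate group sizes (22,059 / 7,811) and every covariate's
per-group marginal distribution to the published 2009 descriptive table:
maternal age bands, social class, marital status, country of birth,
previous miscarriage, gestation bands, birthweight bands, nine clinical
risk indicators, and delivery in an academic teaching hospital. Printed
percentage columns that sum to 99.9/100.1 due to rounding are renormalised
to exactly 1.

* Covariates are drawn independently within group — the published table
  gives only marginals. A Gaussian-copula hook (`correlations`) couples
  selected covariates; it is off by default because no joint distribution
  was published to calibrate it against, so any correlation structure is
  the user's own assumption.
* Quantities published in bands but modelled continuously (age in years,
  birthweight in kg, gestation in weeks) use a `banded` kind: the band is
  drawn from the published band probabilities, the value uniformly within
  the band (the "band midpoint + jitter" device); the band label is kept
  in a `<name>_band` column for descriptive tables.
* One root seed expands into an independent substream per covariate and
  per outcome (keyed by a CRC of the column name), so adding a column
  never perturbs existing draws; generation is a pure function of
  (spec, seed).
* Outcome coefficients in `default_spec()` are **illustrative**: published
  average marginal effects cannot be inverted to index coefficients
  without the microdata. They were fixed once for clinical plausibility —
  risks increasing in age and birthweight, positive loadings on the
  obstetric risk factors, a larger residual private effect for elective
  than emergency sections — with intercepts set so the generated group
  rates land near the published magnitudes (about 4/9% ELCS and 19/27%
  EMCS at the default seed). Generated group gaps and explained shares are
  therefore properties of this synthetic design, not reproductions of the
  published decomposition.
* Generated cohorts contain no missing values; the CSV loader supports a
  declared sentinel, and models apply listwise deletion, so external data
  with flagged missingness flow through the same pipeline.

What passing tests show, and what they do not: the simulation checks
demonstrate that the estimator recovers known explained shares under the
model the generator implements — independent covariates, correctly
specified index models, no measurement error. Real registry data violate
all three (correlated risk factors, coding error, unobserved confounders
such as BMI), so agreement on synthetic cohorts validates the machinery,
not any substantive claim about the real gap.

## Problem sizes and determinism

The package's own standard configurations: full pipeline on the calibrated
cohort (n = 29,870) at R = 1,000 with all three reference schemes for
final runs, R = 200 for smoke runs (seconds per outcome; the decomposition
loop is vectorised across matched pairs, so a replication costs one pass
over ~30 design columns × 7,811 rows). Simulation-recovery checks use
n = 20,000 with R = 200; parameter-recovery checks use n ∈ {500, 2000,
8000}. Everything — generation, subsampling, ordering, tie-breaking — runs
off explicit seeds, and identical config + seed yields byte-identical
output files.

## Known limitations

* No hospital-level random effects; hospital type enters as a dummy, as in
  single-level specifications.
* No decomposition for multinomial or continuous outcomes.
* The delta-method decomposition SE conditions on the matched-pair sets
  actually drawn; it does not integrate over the matching.
* The descriptive table covers binary, categorical and banded covariates;
  a purely continuous covariate without declared bands is not tabulated.
* The abstract of the calibration source quotes an emergency share of all
  caesareans of 79.6%, while its own printed counts give 79.8%; the
  pipeline reports what the counts imply and surfaces the published-count
  checks in the run manifest rather than reconciling them.
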