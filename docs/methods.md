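# Methods

## The estimation model

Age at death is inferred from a profile of ordinal stage scores on seven
acetabular variables (V1: stages 0–3, V2: 0–6, V3: 0–5, V4: 0–4, V5: 0–2,
V6: 0–3, V7: 0–4; the catalog is configurable so other ordinal markers can
be used).  The model is a naive-Bayes classifier over 5-year
age-at-death classes spanning 15–104 years (18 classes):

* **Prior.**  P(c) = n_c / N, the fraction of reference individuals in
  class c.  Classes with no reference individuals get prior 0 and are
  excluded from the posterior's support — the estimator cannot place an
  individual in an age class its reference never saw.
* **Likelihood.**  P(s_v = k | c) = (m_vck + α) / (m_vc· + α·K_v), the
  conditional stage frequency among reference individuals of class c that
  were scored on v (K_v = number of stages).  Individuals with a missing
  score on v are excluded from that variable's frequency but still count
  in the prior.  At α = 0 a class where nobody was scored on v
  contributes a zero factor (0/0 guard).
* **Posterior.**  Scored variables are combined as conditionally
  independent given the class; missing variables contribute no factor.
  If the unnormalised product has zero total mass — possible at α = 0
  when the observed stage combination never co-occurs with any populated
  class — the result is an explicit *no-estimation* outcome.  An
  all-missing profile is a validation error, not a no-estimation.
* **Point estimate.**  The posterior expectation of the class central
  ages.  Central age is the arithmetic midpoint of the inclusive class
  interval (15–19 → 17), the only symmetric choice; taking 17.5 instead
  would move every estimate by at most 0.5 years.  Estimates are
  real-valued years; rounding is presentation's concern.

The conditional-independence structure and the reference-fraction prior
are the standard form of frequency-table Bayesian aging methods; no
correlation adjustment between variables is attempted.  Default smoothing
is α = 0 so that impossible profiles surface as no-estimation outcomes —
the behaviour needed to study method applicability across reference
choices — while α > 0 is exposed for users who prefer an estimate pulled
toward the prior over a failure.  As α → 0 the smoothed posterior
converges to the unsmoothed one wherever the latter exists.

Sex-specific estimation is enforced by the experiment layer (references
and test samples are sex-stratified end to end), not hard-coded in the
estimator; pooled-sex analyses remain possible by construction.

## Inaccuracy evaluation

For estimated individuals, **bias** = mean(estimated − chronological)
(positive = overestimation) and **absolute error** = mean |estimated −
chronological|; |bias| ≤ absolute error always.  Reports are produced
globally and over three wide chronological-age bands [15, 40), [40, 65),
[65, ∞); age 65 belongs to the oldest band so the partition is total.
No-estimation individuals are excluded from the means and reported as
separate counts per scope.

Reference choices are compared on *identical test individuals* with the
Wilcoxon signed-rank test applied to the per-individual signed errors
(bias block) and unsigned errors (absolute-error block), per scope.
Individuals lacking an estimate in either arm are dropped from that
paired comparison.  Zero differences are dropped before ranking (classic
Wilcoxon); the exact null distribution is used for ≤ 25 remaining untied
pairs, otherwise the tie-corrected normal approximation.  Stage-timing
differences between populations use the Mann–Whitney U test on the two
samples of individual ages at each (variable, stage) cell — exact when
n_a·n_b ≤ 400 and the pooled sample is tie-free, tie-corrected normal
approximation otherwise.  Every result records which method produced its
p-value.  All tests are two-sided at the 0.05 threshold, with **no
multiple-testing correction** across the many per-stage tests — the
per-cell flags are descriptive, and the expected false-positive rate
under the null (~5% of cells) is left to the reader.

Observer agreement uses weighted kappa, κ = 1 − ΣwO/ΣwE with
disagreement weights |i−j| (linear, the default) or (i−j)² (quadratic),
and verbal bands 0.61–0.79 "substantial", 0.80–1.00 "almost perfect"
(lower bands follow the same convention).  κ is undefined (and flagged)
when chance disagreement is zero.  Box-plot five-number summaries use
linear interpolation between order statistics (numpy's default quartile
rule), fixed for reproducibility.

## The synthetic generator

Real documented collections cannot be shipped, so the pipeline is
exercised on synthetic ones.  Each variable follows a cumulative-logit
aging process: P(stage ≥ k | age) = logistic((age − (τ_k + δ)) / s) with
strictly increasing thresholds τ_k; stage probabilities are successive
differences, hence non-negative and summing to 1.  This is the simplest
monotone ordinal aging process; it makes no claim about the true
transition-noise structure of real acetabula.

* **Thresholds** are calibrated as midpoints between consecutive
  published per-stage mean ages of documented collections (for a variable
  with anchors 17.40, 48.04, 60.61, 74.74 years: τ = 32.72, 54.325,
  67.675).
* **Transition scale** s = 8 years by default, which puts simulated
  per-stage age SDs at 10.5–15.3 years, inside the 8–19-year range of the
  documented tables.
* **Aging shift** δ (years) moves every threshold additively: δ < 0 means
  stages are attained earlier (faster aging), and the age at which
  P(stage ≥ k) = 0.5 moves by exactly δ.
* **Age structure** is piecewise-uniform over decade bins with weights
  proportional to the documented collections' counts, which are skewed
  old.
* **Presets.**  "PT-like" uses the Portuguese-anchored thresholds,
  Portuguese age weights, δ = 0.  "NA-like" uses the same thresholds with
  δ = −5 years (the order of the significant documented between-
  population mean-age differences) and North-American age weights.  The
  published North-American per-stage means are not used as direct anchors
  because several variables lack stage-0 observations and a few small-n
  cells are non-monotone in stage — artifacts of that collection's
  near-absence of young individuals; the additive-shift representation
  keeps the preset well-defined for all stages.
* **Dependence knob.**  By default variables are drawn conditionally
  independently given age, matching the estimator's assumption.  A
  per-individual frailty scale (> 0) adds a shared normal shift to δ,
  correlating the variables within an individual, for robustness studies.
* **Missingness** is applied per variable, post-draw, at a configurable
  rate (default 0 — the documented tables show every individual scored on
  every variable).

What passing tests on this generator show — and what they do not: the
pipeline reproduces the qualitative phenomena (near-unbiased matched
recovery; overestimate-young / underestimate-old regression toward the
prior; underestimation of slow-aging samples under fast-aging references
and vice versa; reduced applicability, i.e. more no-estimation outcomes,
under crossed references; the early-stage mean-age artifact when one
population lacks young individuals).  They do not certify accuracy
magnitudes on real collections: synthetic variables are conditionally
independent given age, so seven of them are jointly more informative than
real correlated acetabular traits, and the matched-arm absolute error
(≈ 4.5–6 years at the default calibration) sits at, and sometimes
slightly below, the low end of the 7.09–9.65-year range documented for
real material.  Observer scoring error and taphonomy are likewise not
simulated.

## The crossed design

Two populations, sex-stratified: experiments 1 and 2 estimate each test
sample with its own population's reference; experiments 3 and 4 swap the
references.  Outputs are long-form inaccuracy tables (per experiment,
scope: three bands + global), paired matched-vs-crossed Wilcoxon
comparisons, and per-pairing no-estimation counts with matched-mean and
crossed-mean summaries.  Reference/test splits of a single collection can
be recreated with a seeded, optionally stratified splitter (per stratum,
round(fraction × size) records to the reference; strata with fewer than
two records go wholly to reference, with a warning); the historical
splits of the documented collections are of unknown construction, so
stratification is a parameter rather than a fixed rule.

## Numerical and interface choices

* Desk-scale problem sizes throughout the test-suite and acceptance
  script: 300 reference / 150 test individuals per arm, 500–1000 random
  small tables for the enumeration oracle, single-seed crossed designs.
  These finish in seconds while leaving the statistical patterns
  unambiguous.
* Posterior normalisation is exact to 1e-9 by construction; the
  brute-force enumeration comparison is asserted at 1e-12.
* Reference tables serialise to JSON (grid, catalog, class counts, nested
  stage counts, metadata) and are loadable without the raw records, so
  reference datasets are pluggable.
* Collection CSVs: `individual_id,collection,population,sex,age,side,
  v1..v7`, UTF-8, blank = missing; ages whole years in [15, 110]; side L
  by default (the right side substitutes when the left is damaged —
  metadata only, estimation never mixes sides within an individual).
* The core estimator is presented as a scikit-learn estimator
  (`BayesianAgeEstimator`) with `fit(X, y)` on stage profiles (NaN =
  missing) and documented ages, `predict` (NaN = no estimation) and
  `predict_proba`; the module-level functions (`build_reference_table`,
  `posterior`, `point_estimate`, `estimate_batch`) remain the domain
  API over `SkeletalRecord` lists.

## Known limitations

* The naive-Bayes independence assumption is shared by generator and
  estimator by default; real acetabular variables are correlated, and
  matched-arm error magnitudes here are accordingly optimistic (see
  above).
* The no-estimation trigger is exactly zero posterior mass at α = 0;
  production web implementations of this method family may use different
  sparse-class handling, which is not documented and not emulated.
* Stage scoring itself (the visual assessment of bone morphology) is out
  of scope: the package consumes already-scored stages.
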