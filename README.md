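# acetage

Bayesian age-at-death estimation from ordinal acetabular stages, with the
evaluation machinery needed to study how the choice of reference
collection drives its accuracy.

## The problem

Estimating adult age at death from skeletal remains is a core task of
forensic anthropology and bioarcheology.  The acetabulum (the hip socket)
carries seven age-progressive morphological variables (V1–V7), each scored
as an ordinal stage.  Given a *reference collection* of documented
individuals (known sex and age at death), the age of an unidentified
individual is estimated by Bayesian inference over 5-year age-at-death
classes c (15–19, 20–24, …, 100–104):

- prior: P(c) = n_c / N, the fraction of reference individuals in class c;
- likelihood: P(s_v = k | c), the conditional frequency of stage k of
  variable v among reference individuals of class c (optionally smoothed,
  (m_vck + α)/(m_vc· + α K_v));
- posterior: P(c | profile) ∝ P(c) · Π_v P(s_v | c), with scored variables
  treated as conditionally independent given the class;
- point estimate: the posterior expectation of the class central ages
  (15–19 → 17, 20–24 → 22, …).

At α = 0 a stage profile that never co-occurs with any populated class has
zero posterior mass and yields an explicit **no estimation** outcome
rather than a forced guess.

Because different populations attain the same acetabular stages at
different ages (aging-rate differences), the reference collection's
geographical origin biases the estimates: a slow-aging test sample read
against a fast-aging reference is systematically underestimated, and vice
versa.  The package quantifies this with bias (mean signed error,
positive = overestimation), absolute error (mean unsigned error), paired
Wilcoxon tests between reference choices on the same test individuals,
Mann–Whitney U tests on per-stage age distributions, and weighted kappa
for observer agreement.  A cumulative-logit synthetic-collection generator
(calibrated on published per-stage mean ages of a Portuguese and a
North-American documented collection) makes every part of the pipeline
testable without access to real skeletal data.

## Worked example

```python
import acetage as ag

models = ag.preset_models("PT-like", "M")
ref  = ag.simulate_collection(ag.preset_config("PT-like", "M", 300), models, seed=1)
test = ag.simulate_collection(ag.preset_config("PT-like", "M", 150), models, seed=2)
run = ag.run_experiment(ag.ExperimentSpec(1, "PT", "PT", "M"), ref, test)
for r in run.reports:
    print(f"{r.scope:>6}  n={r.n:3d}  bias={r.bias:+.2f}  abs_error={r.absolute_error:.2f}")
```

prints

```
 15-39  n= 34  bias=+5.20  abs_error=6.12
 40-64  n= 65  bias=-1.37  abs_error=3.97
  >=65  n= 51  bias=-3.09  abs_error=5.04
global  n=150  bias=-0.47  abs_error=4.82
```

A population-matched reference recovers age essentially without global
bias, but the band pattern characteristic of reference-frequency Bayesian
aging appears: the youngest individuals are pulled up toward the (old-
skewed) reference prior (+5.2 years) and the oldest are pulled down
(−3.1 years).

The estimator also exposes a scikit-learn interface
(`BayesianAgeEstimator().fit(X, y).predict(X_new)`, with `predict_proba`
returning the per-class posterior and NaN rows marking no-estimation
outcomes), so it composes with sklearn model selection.

A command-line layer wraps the same functions:

```bash
acetage simulate --preset PT-like --sex M -n 300 --seed 1 -o ref.csv
acetage simulate --preset PT-like --sex M -n 150 --seed 2 -o test.csv
acetage estimate --reference ref.csv --test test.csv -o estimates.csv
acetage evaluate --estimates estimates.csv --truth test.csv -o report.csv
acetage compare-stages --collection-a a.csv --collection-b b.csv -o timing.csv
acetage kappa --ratings ratings.csv
acetage run-design --config design.yaml --outdir out/
```

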