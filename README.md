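# metabias

Detection and correction of publication bias in multilevel meta-analytic
data, with second-order (meta-meta-analytic) pooling, folded-normal
quantification of effect-size shrinkage, and retrodesign calculus
(statistical power, Type M and Type S errors).

## The problem

When statistically significant results are published preferentially,
the published literature overstates effects in two recognisable ways:
small studies report larger effects than big ones (*small-study effects*,
because a small study must overshoot to reach significance), and reported
effects shrink over calendar time (*decline effects*, as slower,
non-significant results trickle out). Meta-analyses built on such a
literature inherit the inflation, and so do any power calculations that
use the meta-analytic mean as the "true" effect: power is overstated,
while the exaggeration ratio (Type M) and the probability of a
significant result with the wrong sign (Type S) are understated.

`metabias` implements the full workflow for corpora of meta-analyses of
the three standard ecological/evolutionary effect-size metrics —
standardized mean difference (Hedges' *g*), log response ratio, and
Fisher's *z*-transformed correlation:

1. **Per meta-analysis** — fit the three-level random-effects model
   `ES_ji = β0 + s_j + o_ji + m_ji` by REML (study and observation random
   effects, known sampling variances); test for bias with an extended
   Egger-type multilevel meta-regression
   `ES_ji = β0 + β1·error_i + β2·(year_i − year_latest) + …`, where
   `error_i` is the standard error or the effective-sample predictor
   `√((n_e+n_c)/(n_e n_c))`; estimate a bias-corrected overall effect as
   the intercept of the quadratic (PEESE-style) variant, routed through a
   sign-based decision tree that falls back to reduced models when slopes
   contradict the bias signature.
2. **Across meta-analyses** — refit each case on a standardized scale and
   pool the scale-free slopes and intercept drops by random-effects
   second-order meta-analysis (inverse-squared-SE weights, effect-size
   type as moderator); quantify the shrinkage `D = |η_u − η_c|` with
   folded-normal mean and variance and pool it; back-transform to each
   metric's units.
3. **Retrodesign** — compute power, Type M and Type S from closed
   truncated-normal forms for every effect size and meta-analysis, under
   uncorrected and corrected "true" effects, aggregated by a
   study-random-intercept mixed model (sampling level) and a k-weighted
   regression (meta-analysis level).

A synthetic-literature generator with known ground truth (hierarchical
effects, metric-exact sampling variances, significance filtering with an
optional time-relaxing variant) makes every stage testable; see
`docs/methods.md` for the models and design choices.

## Worked example

```python
from metabias import GeneratorConfig, generate_corpus, run_pipeline

cfg = GeneratorConfig(
    n_meta=30, studies_per_meta=(30, 40), effects_per_study=(1, 3),
    metric="SMD", true_effect=0.4, between_study_sd=0.1,
    within_study_sd=0.05, selection_strength=2.0, seed=123,
)
corpus, truth = generate_corpus(cfg)          # known ground truth: 0.4
bundle = run_pipeline(corpus)

pooled = bundle.second_order["small_study_full"]
print(f"pooled small-study slope = {pooled.estimate:.3f} "
      f"(95% CI {pooled.ci_low:.3f} to {pooled.ci_high:.3f}, p = {pooled.pval:.2g})")
bias = bundle.bias_cases
print(f"mean uncorrected effect  = {bias['beta0_overall'].mean():.3f}")
print(f"mean corrected effect    = {bias['beta0_corrected_type2'].mean():.3f}")
agg = bundle.design_aggregates
print(f"sampling-level power     = {agg['sampling_uncorrected'].mean['power']:.2f} "
      f"-> {agg['sampling_corrected'].mean['power']:.2f} after correction")
```

prints

```
pooled small-study slope = 0.224 (95% CI 0.140 to 0.309, p = 1.8e-07)
mean uncorrected effect  = 0.622
mean corrected effect    = 0.455
sampling-level power     = 0.58 -> 0.37 after correction
```

The significance filter inflated the naive pooled means (0.622 against a
true effect of 0.4); the pooled standardized uncertainty slope exposes the
small-study effect, the decision-tree corrected estimate (0.455) recovers
most of the inflation, and the power computed against the corrected truth
is substantially lower — the filter had been flattering the literature.

There is also a thin CLI:

```bash
metabias simulate --seed 3 --n-meta 20 --out corpus.csv
metabias run --corpus corpus.csv --outdir results/
metabias counts --bias-cases results/bias_cases.csv
metabias figures --outdir figures/
```

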