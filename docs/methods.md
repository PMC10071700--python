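# Methods

`metabias` implements a two-level procedure for quantifying how selective
publication distorts meta-analytic evidence, and what that distortion does
to statistical power and to magnitude (Type M) and sign (Type S) errors.
This note records the models, the choices that were genuinely open, and
the limits of what the synthetic-data tests demonstrate.

## The multilevel meta-analytic model

Every per-meta-analysis fit is a three-level Gaussian model for effect
size `ES_ji` (effect *i* of study *j*) with known sampling variance `v_i`:

    ES_ji = x_ji' beta + s_j + o_ji + m_ji
    s_j ~ N(0, sigma2_study),  o_ji ~ N(0, sigma2_obs),  m_ji ~ N(0, v_i)

Variance components are estimated by REML; fixed effects are profiled out
by GLS, so the restricted likelihood is a function of the two components
only. It is evaluated in O(k) via a rank-one Woodbury identity inside each
study block. Numerical choices:

- Optimization is over log-variances with L-BFGS-B from three
  deterministic starts spread over the total response scale
  (`var(y) + mean(v)`), with a Nelder–Mead polish if L-BFGS-B does not
  report success. Convergence tolerance is 1e-8 on the restricted
  log-likelihood; components are bounded below at 1e-10 to keep the
  marginal covariance nonsingular.
- Because the likelihood is extremely flat near a zero component, the
  interior optimum is compared against the three boundary fits
  (`sigma2_study = 0`, `sigma2_obs = 0`, both zero); within a 1e-7
  log-likelihood tie the most constrained candidate wins, so degenerate
  components are reported as exactly zero rather than as an arbitrary
  small number. This also makes location/scale equivariance hold to
  reported precision.
- With one effect per study the two components are jointly unidentifiable;
  the fit warns and reports a single total heterogeneity component.
- Inference is Wald-z by default (matching the convention of the standard
  multilevel meta-analysis software this model family comes from);
  Student-t on `k - p` degrees of freedom is a constructor switch.
- Heterogeneity is summarised as multilevel I² with the Higgins-style
  typical sampling variance `(k-1) Σw / ((Σw)² − Σw²)`, `w = 1/v`.

The fit was cross-validated against `metafor::rma.mv` (REML, same random
structure) on a frozen 12-record fixture: coefficients, standard errors
and variance components agree to 1e-4 (see the test suite).

## Bias detection and correction

Detection per meta-analysis uses the extended Egger-type meta-regression:
effect sizes are regressed on an uncertainty measure and on publication
year centred at the latest year, inside the multilevel model above. A
positive overall effect under selective publication predicts a positive
uncertainty slope (small-study effect) and a negative year slope (decline
effect); a negative overall effect mirrors both.

- Uncertainty predictor: for SMD and lnRR with complete group sizes, the
  effective-sample predictor `sqrt((n_e+n_c)/(n_e n_c))` replaces the
  standard error to break the built-in estimate–variance coupling of those
  metrics; otherwise (and for Fisher's z by default) the standard error is
  used. The choice is recorded per case and is configurable.
- Correction uses the quadratic (PEESE-style) variant — the squared
  predictor (sampling variance or `1/ñ`) — whose intercept, conditional on
  zero sampling error at the latest year, is the bias-corrected overall
  effect. Both the linear and quadratic fits are always computed; the
  linear fit supplies the detection slopes, the quadratic fit the
  corrected intercept.
- Decision tree: slope signs are read from the linear fit. Both expected →
  keep the full quadratic intercept (scenario 1); uncertainty slope
  expected but year slope not → refit with the quadratic uncertainty term
  only (scenario 2); the reverse → year term only (scenario 3); both
  unexpected → fall back to the intercept-only estimate (scenario 4). The
  full-model intercept is always retained as the "type 1" estimate and the
  tree's choice as "type 2". An alternative mapping that swaps scenarios
  2 and 3 exists in the literature for this procedure; it is available as
  `correction_variant="figure_caption"` but is not the default.
- Constant predictor columns (single publication year, constant n) are
  dropped with a record; a meta-analysis with an exactly zero overall
  estimate leaves the expected signs indeterminate and keeps the
  full-model intercept with a warning. Cases with k < 4 are skipped and
  logged.

## Standardization and second-order pooling

Coefficients from different effect-size metrics are pooled after refitting
each case on a scale-free parameterization: the response is divided by its
unweighted SD (ddof=1, no centring — centring would destroy the intercept
interpretation), and the predictors are replaced by shifted z-scores,
which algebraically reduce to `error_i / SD(error)` and
`(year_i − year_latest) / SD(year)`; the quadratic model squares the
shifted uncertainty z-score. The z-scaling constants use plain unweighted
means and SDs over the case's records. By construction the standardized
coefficients are invariant to rescaling the raw effect sizes, and the
standardized intercept times the response SD reproduces the raw intercept.

Standardized slopes are pooled across meta-analyses by a random-effects
model with inverse squared standard errors as weights (the same REML
engine with a single between-case component tau²), optionally with
effect-size type as a cell-means moderator; the moderator's marginal R² is
`var(fitted) / (var(fitted) + tau²)`. Pooling is done for the full set of
cases and for the reduced set whose slopes have the expected direction.

## Folded-normal shrinkage

The drop from the uncorrected to the corrected standardized effect,
`D = |eta_u − eta_c|`, is treated as folded-normal:
`Var(D) = SE_c² + SE_u² − 2 r SE_c SE_u` with the SE correlation `r` fixed
at 1 (the two intercepts come from the same data), hence
`Var(D) = (SE_c − SE_u)²`; r is exposed for sensitivity analysis. The
folded mean and variance follow the standard closed forms, with the
`Var(D) → 0` limit handled analytically (`D_f = D`, variance 0). Folded
means are pooled with folded variances as sampling variances (floored at
1e-10 so a degenerate case cannot take infinite weight), and per-case
back-transformation multiplies by the response SD divided out during
standardization; per-metric back-transformed summaries are unweighted
means of the per-case folded values (the averaging rule was not pinned
down externally; a weighted variant is a one-liner on the returned table).

## Retrodesign: power, Type M, Type S

For true effect `t`, standard error `se` and two-sided level alpha, the
estimate is modelled as `N(t, se²)`. With `z_c` the two-sided critical
value and `lambda = t/se`: power is the probability of significance, Type
S the probability a significant estimate has the wrong sign, and Type M
the expected `|estimate|/|t|` among significant estimates, computed from
truncated-normal moments. All three depend on (lambda, alpha) only; at
`t = 0` the definitions force power = alpha, Type S = 1/2, and Type M is
undefined (stored as infinity and excluded from means; a display cap of 10
is conventional for tables, values are stored uncapped). A seeded
Monte-Carlo retrodesign is kept purely as an oracle.

Aggregation mirrors the corpus hierarchy. At the sampling level every
effect size inherits its meta-analysis' mean (uncorrected, or the type-2
corrected estimate) as its "true" effect — a deliberate simplification
that ignores context-dependent true effects — and per-effect metrics are
averaged by a study-random-intercept mixed model (the same REML engine
with no known-variance term), with medians reported alongside because
means and medians of skewed Type M distributions differ materially. At
the meta-analysis level the truth is the (un)corrected mean, the standard
error is that of the uncorrected overall estimate (the meta-analysis'
actual precision), and aggregation is a k-weighted mean. The post hoc
filter variant drops meta-analyses whose uncorrected mean is not
significant before aggregating; it changes membership only, never
per-case values.

## The synthetic-literature generator

The generator exists to give every stage a ground truth; the empirical
corpus it stands in for was observational, so all generative choices are
stand-ins and are labelled as such:

- Hierarchy: `n_meta` meta-analyses, each with a number of studies and
  effects per study drawn from configured ranges; study effects
  `N(0, sigma2_study)` and observation effects `N(0, sigma2_obs)` around a
  common true effect (defaults 0.3, SDs 0.2 / 0.1: a moderate effect with
  heterogeneity comparable to the sampling noise of 5–50-per-arm groups).
- Sampling: SMD simulates two unit-SD groups and computes Hedges' g;
  lnRR simulates two groups with constant coefficient of variation 0.3
  around a control mean of 10; Zr simulates bivariate-normal samples with
  `rho = tanh(theta)`. Sampling variances therefore obey the metric
  formulas exactly, which the tests assert.
- Selection: significant records (two-sided p < alpha from es/se) are
  always retained; non-significant records survive with probability
  `exp(-selection_strength)` — the simplest monotone mechanism. The
  decline variant scales the strength by
  `(year_latest − year)/(year span)` so the filter relaxes to nothing at
  the latest year, producing a decline in the published record; a direct
  per-year drift of the true effect (`decline_slope`) is also available.
  Selection that leaves fewer than two studies raises a degenerate-corpus
  error rather than returning an unusable dataset.
- Seeding: one master seed; each meta-analysis receives a spawned child
  seed, so any single meta-analysis is reproducible in isolation.

A property worth recording, because it constrains what "selection implies
a small-study effect" means: with a *two-sided* significance filter the
published conditional mean `E[ES | published]` increases with the standard
error only when the significant-negative tail is negligible, i.e. when the
true effect is large relative to the total SD (heterogeneity plus sampling
error). With a small true effect and substantial heterogeneity the
negative significant tail is published too and the classic positive
gradient flattens or even reverses. The directional acceptance checks
therefore use a true effect of 0.4 against a total heterogeneity SD of
about 0.11, where the closed-form conditional mean rises from ≈0.56 at the
smallest sampling errors to ≈0.79 at the largest.

## What the tests do and do not show

Problem sizes were chosen to exercise every stage at desk scale: the REML
grid oracle uses a 12-record fixture against a 200×200 brute-force grid;
the retrodesign and folded-normal closed forms are checked against 1e7
Monte-Carlo draws within 3 Monte-Carlo SEs; parameter recovery uses 200
simulated meta-analyses of 30 studies; null calibration uses 60 corpora of
10 meta-analyses. The generator reproduces the *structure* the analysis
assumes — it does not model p-hacking, optional stopping, citation
dynamics, correlated sampling errors, or the marginal distributions of any
particular empirical corpus, so passing tests certify the estimators and
the pipeline logic, not the real-world prevalence of bias. Wald-z
intervals on small numbers of cases undercover slightly (observed ≈92–93%
at a nominal 95% in the null calibration), and the per-meta slope
significance rate inflates mildly under high heterogeneity; both are
expected behaviour of this model family and are tolerated and asserted as
such in the calibration test.

## Known limitations

- No robust (cluster) variance estimation, correlated-error V matrices,
  Knapp–Hartung adjustment, or Bayesian fitting.
- No selection-model corrections (Copas, step-function), trim-and-fill or
  p-curve; the correction family is regression-based only.
- Truth proxies at the sampling level assume a shared true effect within
  each meta-analysis.
- Effect-size conversions between metrics are deliberately not performed;
  each meta-analysis is analysed in its native metric.
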