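# Methods

## Model and procedure

The package implements supervised principal components: a univariate
association score per feature, hard thresholding of |score|, a one-component
PCA on the retained features, and prediction by projection. The working
assumptions are those of the underlying models — proportional hazards with
right censoring for survival outcomes, a linear-Gaussian response for
continuous outcomes, and a logistic response for binary outcomes — plus the
structural assumption that a single latent direction in expression space
carries the outcome-relevant variation.

### Screening statistics

All three screening statistics are score tests evaluated at the null, so they
are closed-form, deterministic, and require no per-feature iterative fitting:

- **Survival** — Cox partial-likelihood score test at β = 0 with the Breslow
  convention for tied event times: every event at a tied time uses the full
  risk set at that time. U_j sums, over events, the subject's expression minus
  the risk-set mean; I_j sums the risk-set (population) variances;
  z_j = U_j/√I_j. Censored samples contribute to risk sets only.
- **Continuous** — the t statistic of the univariate least-squares slope,
  algebraically r√(n−2)/√(1−r²). Perfect collinearity (r² = 1 to within
  1e−12) is reported as ±(largest representable float) with a warning rather
  than an error, so screening keeps such a feature ahead of everything else.
- **Binary** — the logistic score test of the slope with the intercept
  treated as a nuisance fixed at logit(ȳ); the information is the efficient
  (profiled) form ȳ(1−ȳ)Σ(x−x̄)². A Wald variant (`stat="wald"`), the z of a
  Newton-fitted univariate logistic model, is available as a configuration
  option; the score form is the default because it is non-iterative and
  exactly reproducible.

Constant features score 0 with a warning instead of raising: real matrices
contain constant rows and thresholding should drop them silently.

Signs are oriented so positive scores mean higher expression with higher
hazard / larger outcome / class 1. The statistics are invariant to per-feature
location shifts; the continuous and binary statistics are also invariant to
positive per-feature scaling. Tests verify all three against numerical
differentiation of independently written log-likelihoods.

### Threshold grid

Candidate thresholds are |s| quantiles (linear-interpolation definition,
`numpy.quantile` default) at probabilities equally spaced from 0 to 0.95,
deduplicated. The 0.95 cap guarantees the strictest candidate still retains
roughly the top 5% of features, so no grid point can empty the selection on
the data that built the grid. Screening is strict (|s_j| > θ), which makes
θ = max|s| an error rather than a silent empty model.

### Cross-validation

Folds are seeded, dealt cyclically within strata (event indicator for
survival, class label for binary) so events and classes spread as evenly as
possible, and always written to disk; supplying a previously emitted fold
file replays a run bit-for-bit. When a fold file is supplied it also *defines*
the training set (its sample domain), the remaining samples forming the test
set — this is what makes seed-free replay exact.

Within each fold, scores, screening, the centering vector and the loading
vector are computed from out-of-fold samples only. The held-out objective is
the likelihood-ratio statistic of the outcome on the projected PC: Cox LR for
survival, −n·log(1−r²) for continuous (the Gaussian LR), logistic LR for
binary. These univariate fits use small in-package Newton solvers with step
halving and parameter clipping (linear predictor bounded at ±30, Cox β at ±50
after standardizing the covariate), which keeps tiny, separable folds finite
and deterministic without convergence warnings; tests cross-check them
against lifelines and statsmodels. A threshold that empties a fold's screened
set contributes statistic 0 for that fold (logged), keeping the CV curve
total over the grid. The selected threshold maximizes the fold mean; exact
ties resolve to the larger threshold (fewer features).

Validation requires K ≥ 2, at least 2 samples on each side of every fold,
and — for survival — at least one event in both the held-out and training
portion of every fold; the error suggests stratified folds or fewer folds.

### PC fit, projection, dichotomization

Only the first principal component is fitted (a deliberate restriction;
multi-component variants are out of scope). Features are centered by training
means and *not* variance-scaled: rescaling would discard the implicit
weighting the screening statistic imposes, and users who want unit-variance
features can pre-standardize. The loading vector is the leading singular
direction over features, unit norm, with the largest-|entry| made positive so
results do not depend on the SVD implementation's sign choice. Projection is
affine: wᵀ(x − center); projecting the training matrix reproduces the
training PC scores through the identical arithmetic path.

Dichotomization sends scores ≤ median to "low". When ties make the median
equal the maximum, the cut falls instead just below the largest value so both
groups stay non-empty on any non-constant input.

### Test-set summaries

Log-rank uses the standard pooled-risk-set hypergeometric-variance form and
Kaplan–Meier product-limit curves (both via lifelines). The t test defaults
to Welch's unequal-variance form (safer under unequal group spreads) with a
pooled option. The chi-square test is Pearson's without continuity correction
by default (switchable); the correction choice materially changes
small-sample p-values, so it is explicit. The odds ratio is ad/bc on the 2×2
table, with 0.5 added to every cell only when a zero cell exists (logged).
The odds ratio accompanies the chi-square as an extra effect field.

### Forest plots

Rows are rendered verbatim in input order — no sorting, pooling, or CI
recomputation — with a log-scaled axis and reference line at 1.0 by default
(ratio-scale measures), both overridable. SVG output is byte-deterministic
(fixed hash salt, no timestamp metadata, text kept as text).

## Synthetic data generator

The generator emulates the structure the pipeline targets: a latent factor
u_i ~ N(0,1); signal genes b_j·u_i + N(0,1) with b_j ~ U(0.5, 1.5); noise
genes N(0,1); outcomes driven by γ·u_i (exponential survival times with
hazard exp(γu) and uniform censoring calibrated by bisection to the requested
censoring fraction; Gaussian continuous response; Bernoulli(logistic(γu))
labels). All distributions are the simplest members of their families.

It does **not** mimic RNA-seq count distributions, library-size effects,
heavy tails, or gene–gene correlation beyond the single factor. Passing tests
therefore demonstrate correctness of the algorithmic machinery and its
statistical calibration under a clean single-factor model — not robustness to
the messiness of real tumor expression data.

## Problem sizes and numerical choices

Default study conditions used by the tests and the acceptance script, chosen
once as realistic desk-scale versions of expression studies:

- strong-signal recovery: 150 samples, 500 genes, 20 signal genes, γ = 2,
  train proportion 0.67, 20 thresholds, 5 folds;
- null calibration: 200 replicates of 80 samples × 60 genes at γ = 0, train
  proportion 0.6, 6 thresholds, 4 folds, for each outcome type;
- CLI defaults: train proportion 0.67, 20 thresholds, 10 folds.

Numerical conventions worth knowing: quantiles are linear-interpolation;
screening is strict; CV ties break upward; survival risk-set variances are
clipped at 0 against roundoff; written tables format floats with `repr` so a
written-then-read table is bit-identical; Newton solvers stop at gradient
1e−10 (score fits) or step 1e−12 (LR fits) with at most 100 iterations.

## Limitations

- One principal component; no soft-thresholding or shrinkage variants.
- Screening is by threshold on |s|, not by p-value; no multiple-testing
  machinery is involved or provided.
- Missing expression values are rejected at load; impute beforehand.
- The logistic LR under complete separation is capped by the parameter
  clipping; its value is then a bounded surrogate for an infinite MLE, which
  is the desired behavior for comparing thresholds but not a valid test
  statistic on its own.
- No multivariable adjustment on the test set and no proportional-hazards
  diagnostics.
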