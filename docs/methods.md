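# Methods

This note documents the statistical models implemented in `elembench`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and cleaning

A sample is one hair specimen with metadata (population, growth year,
ordered trend label, collection method, age class, sex) and concentrations
(µg/g) for an 11-element panel (Na, Mg, Ca, Cr, Mn, Fe, Co, Cu, Zn, Se,
Mo). Cleaning rules, in order:

* **Below-LOQ substitution.** Values flagged below the limit of
  quantitation are set to LOQ/2, the standard convention for left-censored
  trace-element data. An element whose below-LOQ fraction (over non-missing
  entries) exceeds 0.5 is removed entirely: at that censoring level the
  substitution constant would dominate the distribution. The operation is
  idempotent. LOQs are assay properties and must come from configuration;
  the shipped defaults are plausible ICP-MS hair values.
* **Completeness.** Records missing any required metadata field are
  excluded and counted. Missing concentrations (distinct from below-LOQ)
  stay missing and exclude the record only from analyses that need that
  element; nothing is imputed.
* **Outlier screen.** Per element, samples with |x − mean| > k·SD
  (default k = 3) are removed. Choices: *two-sided*, because that is the
  standard convention even though an upper-tail-only reading is possible;
  *single pass* with mean and SD from the pre-removal table, because
  re-iterating the rule on heavy-tailed concentration data removes an
  unbounded fraction; *computed across the whole retained dataset*, not
  within population, so that a population that is systematically extreme is
  not silently normalised. An element with zero SD yields no removals. The
  QC report books every input record exactly once
  (`n_input = n_missing + n_outliers + n_retained`).

## Variance partition (mixed models)

Per element, a Gaussian linear mixed model fitted by REML (statsmodels
`MixedLM`): fixed effects for collection method, age class and sex; random
intercepts for population and for growth year nested within population.
Concentrations are right-skewed, so the response may be log-transformed.
The choice is automatic — |skewness of the fixed-effects OLS residuals| > 1
selects the log — and overridable per element; an automatic rule replaces
visual Q-Q inspection so the transform list is reproducible. Explained
variance is the Nakagawa–Schielzeth pair

    R²m = σ²_fixed / (σ²_fixed + σ²_pop + σ²_year + σ²_resid)
    R²c = (σ²_fixed + σ²_pop + σ²_year) / (same denominator)

with σ²_fixed the sample variance (ddof = 1) of the fitted fixed-effect
linear predictor. When every population carries a single growth year the
nested component is unidentifiable and is dropped (reported as 0). No
random slopes, no model selection, no fixed-effect p-values: the pipeline
uses these fits only to quantify where the variation sits.

## Discriminant stage

**MANOVA.** Wilks' Λ = det(W)/det(W+B) from the within- and between-group
cross-product matrices, with Rao's F approximation; per-element one-way
ANOVA F tests provide the univariate screen (default retention p < 0.05,
but the pipeline default is the fixed seven-element set Cu, Se, Co, Zn,
Mn, Fe, Ca known to drive trend separation in muskox qiviut — the set is
configurable, and `retained_elements=None` switches to the automatic
screen). A near-singular W raises a collinearity error naming the
implicated columns.

**LDA.** Discriminant directions are eigenvectors of the generalized
problem B·v = θ·W·v, rescaled so the *within-group covariance of
discriminant scores is the identity* — the convention of the classical
discriminant analysis implementations under which printed coefficient
vectors are comparable across studies. Predictors enter on their measured
µg/g scale by default (`standardize=True` gives per-SD coefficients).
Scores are computed about the prior-weighted mean of class centroids, so
the grand-mean sample maps to the origin. Sign convention: each axis is
oriented so the highest ordered class (increasing) lies on the nonnegative
side relative to the lowest (declining); discriminant signs are otherwise
arbitrary. Wilks' Λ is recomputed from the eigenvalues (Π 1/(1+θᵢ)) and
must agree with the MANOVA determinant ratio — the two code paths
cross-check each other in the tests. Class priors default to observed
frequencies.

**Classification and LOOCV.** With identity within-class score covariance,
the Gaussian equal-covariance rule is nearest-centroid in score space plus
log-priors. Leave-one-out cross-validation refits the model without each
sample (priors re-estimated per fold). Reported metrics: the confusion
matrix; accuracy; *adjusted error rate* implemented as the balanced
(macro-averaged per-class) error, since the raw error is dominated by the
largest class — the raw error is also reported so either convention can be
recovered; macro-averaged one-vs-rest sensitivity and specificity, with
per-class values emitted alongside. Posterior ties break toward the lowest
ordered class, deterministically.

**LD1 benchmarks.** The limit is the midpoint of the declining and stable
LD1 centroids, the target the midpoint of stable and increasing. These are
meaningful because LD1 is oriented (see above) and its within-group score
variance is 1, so midpoints are in pooled-SD units.

## Ordinal stage

**Model.** Proportional odds / cumulative logit,
P(trend ≤ k | x) = logistic(ζₖ − xᵀβ), fitted by maximum likelihood
(statsmodels `OrderedModel`, BFGS, gradient tolerance 1e-6; a
non-converged fit raises rather than returning estimates, which catches
complete separation). Predictors are z-scaled with the sample SD
(ddof = 1), so exp(β) is the odds ratio per 1 SD of concentration, and
β > 0 means higher concentration shifts mass toward *increasing*. One
joint fit on all retained elements is the default — the per-element curves
then hold the other predictors at their means — with univariate refits
available as a sensitivity mode. Per-element contribution is judged by the
likelihood-ratio test against the drop-one model; elements with LR p ≥ 0.05
keep their test statistics in the outputs but get no quoted odds ratio or
benchmark. Wald z = β/SE and exp-scale Wald intervals supply the odds-ratio
table.

**Probability curves and benchmarks.** For element *e*, the three category
probabilities are traced over a µg/g grid spanning the observed range. The
*limit* is the concentration where p(declining) crosses the probability
level (default 0.45); the *target* where p(increasing) crosses it. Because
the curves are logistic in the scaled concentration, the crossings are
computed by exact closed-form inversion (the grid serves the range check
and the output files); the alternative rule `category-crossing` — the
concentration at which declining (resp. increasing) overtakes stable —
is solved by bracketed root finding and is available because "the point
where one category becomes more likely than the adjacent one" is a natural
competing definition of the threshold. A benchmark outside the observed
concentration range is reported as absent: extrapolated management
thresholds are not defensible. For negatively associated elements
(β < 0) only the limit exists, with decline more probable *above* it.
Benchmarks are unit-equivariant: rescaling an element's unit by c rescales
its benchmarks by c exactly (the scaler absorbs the unit).

Level 0.45 is the default because with three categories it sits above 1/3
(so a crossing implies the category is close to dominating) while still
being reachable inside typical observed ranges; it is exposed as a
parameter.

## Synthetic data generator

Concentrations are log-normal:

    c = exp( ln m[e, trend] − σ²_tot/2 + b_pop + b_year + covariate shifts + ε )

with b_pop ~ N(0, pop_sd²) per population, b_year ~ N(0, year_sd²) per
population-year, ε ~ N(0, log_sd[e]²), and the −σ²_tot/2 correction making
the arithmetic group mean equal the configured mean at baseline
covariates. Defaults are calibrated to a published 11-population muskox
qiviut survey: the trend-by-element means with their 95% CIs seed
`trend_means`, and the residual log-SDs are back-solved from the CI
half-widths (half-width → group SD → CV → log-SD via √ln(1+CV²)), floored
at 0.05 and capped at 1.2 — the widest printed intervals (Cr, Mo) imply
log-SDs near 1.9, which would push most draws below a plausible LOQ and is
not credible for washed hair. The printed intervals conflate within- and
between-population variation, so the split between residual SD and the
random-intercept SDs is a modeling choice: pop_sd = 0.10 and
year_sd = 0.06 on the log scale, consistent with population and year
dominating the explained variation while keeping the strong trend
contrasts (e.g. Fe 313 vs 20 µg/g) as mean structure. The population
roster (11 populations: 4 increasing, 3 stable, 4 declining; 1–6 growth
years each; hunted/capture/shed collection; ~416 samples) mirrors the
survey layout, with equal allocation within population-years since the
per-year field counts are not published. Ground-collected (shed) samples
carry no age/sex, matching field practice; a small rate of missing
metadata is injected elsewhere so the completeness rule has work to do.
Below-LOQ flags come from thresholding at the configured LOQ when one is
supplied (censoring is a property of the measurement, not a coin flip);
an independent per-element rate is used only when no LOQ is given.

**What the generator does not emulate.** Elements are conditionally
independent given trend, population and year (they share random intercepts
but have independent residuals). Real hair profiles have cross-element
correlations — notably antagonisms such as elevated Zn/Ca with Cu
deficiency — which is why, in a *joint* proportional-odds fit on simulated
data, the conditional coefficients of weakly associated elements (Zn, Ca)
are attenuated toward zero: the strong elements (Fe, Co, Cu) nearly
separate the increasing class, leaving Zn/Ca only the weak declining-vs-
stable contrast. Their *marginal* (per-element) associations do carry the
expected negative directions, and that is what the sign-recovery tests
assert, averaging over replicate simulations to integrate out the 11
population intercepts. There is also no spatial/geochemical structure and
no temporal autocorrelation beyond the shared population intercept.
Passing tests on these data therefore demonstrate the correctness of the
estimators and the benchmark machinery, not that any particular field
dataset will reproduce specific coefficient values.

## Numerical choices and degenerate inputs

* Outlier screen needs ≥ 3 non-missing values and nonzero SD per element.
* Eigen-solution uses the symmetric generalized solver; W with condition
  number above 1e10 is treated as singular.
* LOOCV raises if a fold leaves any class with fewer than two training
  samples; group CIs require ≥ 2 observations per group.
* Proportional-odds fits validate full column rank and ≥ 2 outcome levels;
  cutpoints are strictly increasing by construction.
* LR tests clamp tiny negative χ² (optimizer noise) to 0.
* All simulation randomness flows through one `numpy.random.default_rng`
  seed recorded in the run manifest.

## Problem sizes used in the checks

The shipped test suite and the acceptance script run at desk scale: the
default simulated survey (~416 samples), variance-component recovery at
n = 2000 (200 populations × 2 years × 5), ordinal coverage at n = 5000
per replicate, and sign-recovery at n ≈ 200 per population across 10
replicate seeds. These sizes were chosen so each stochastic check has
enough information for its stated tolerance.

## Known limitations

* The overall population-status call in `classify_population` (combining
  LD1 position with per-element limit violations) is this package's own
  synthesis rule, isolated so users can substitute their own.
* The "adjusted" error rate, the LDA prior convention, and the MANOVA
  retention rule each have competing definitions in the field; the
  implemented choices are documented above and the alternatives are either
  reported alongside or configurable.
* With 11 population-level clusters, population-level confounding is real:
  quantities that depend on weak contrasts (e.g. the Zn/Ca coefficient
  signs in a single simulated survey) vary across seeds. This mirrors the
  field situation, where the effective sample size for trend contrasts is
  the number of populations, not the number of hairs.
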