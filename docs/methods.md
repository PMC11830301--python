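# Methods

This note documents the models implemented in `pmdd`, the assumptions they
make, the synthetic-data generator that exercises them, and the numerical
choices that matter for reproducing results.

## Liability-threshold framework

Every diagnosis is modelled as the indicator that a latent standard-normal
liability exceeds the threshold z = Φ⁻¹(1 − K), where K is the lifetime
prevalence.  Liability variance decomposes into additive genetic (A),
shared environment (C) and unique environment (E) shares a² + c² + e² = 1,
with no gene–environment interaction and no dominance.  Expected
additive-genetic sharing is 1/2 for full siblings, 1/4 for half siblings
and 1/8 for first cousins; full siblings share all of C, cousins none.
Half-sibling C sharing is not identified by the full-sibling/cousin
contrast, so the generator and the pair models give half siblings κ·c²
with κ configurable and 0 by default.

### Tetrachoric correlation

For a 2×2 table of pair outcomes, the latent correlation ρ solves
P(X > z₁, Y > z₂; ρ) = p₁₁ with thresholds taken from the margins (or from
known prevalences via `prevalence_constraint`).  The bivariate-normal
orthant probability is computed from Plackett's identity by Gauss–Legendre
quadrature in the angular variable — deterministic and accurate to
~1e-14 — and the root is bracketed to |Δ| < 1e-10.  The reported SE is the
delta-method value √(p₁₁(1−p₁₁)/n) / φ₂(z₁,z₂,ρ) treating thresholds as
fixed; this ignores margin-estimation error, which is negligible at
register-scale counts and in any case only enters the WLS fits through
relative weights.  Pair tables are stored symmetrically (each unordered
pair counted once, off-diagonal cells split between orderings), so margins
are averaged over pair members.  A zero concordant or anti-concordant cell
yields the boundary estimate ±1 with a flag and no finite SE.

### ACE/AE by weighted least squares

Observed kinship-class tetrachorics r_k are fitted to structural values
s_k·a² + c_k·c² by least squares weighted with the inverse squared
tetrachoric SEs, with parameters constrained to [0,1] (and a²+c² ≤ 1).
Two kinship classes and the AE model leave 1 degree of freedom for a
goodness-of-fit chi-square; ACE vs AE comparison uses the difference of
weighted residual sums of squares, with an optional 50:50 chi-square
mixture reference because c² = 0 lies on the parameter boundary.
On exactly model-consistent input the fit statistic is zero and the
parameters are exact, e.g. (r_FS, r_C) = (0.15, 0.0375) gives a² = 0.30
under AE for any weights.

### Genetic correlation

For two traits that can co-occur, r_g is estimated from cross-trait
cross-person tetrachorics, whose structural value is s_k·r_g·√(a₁²a₂²);
marginal a² values are fixed from univariate AE fits (two-stage), and the
kinship classes are pooled by inverse-variance WLS.

Mutually exclusive traits (psychotic vs non-psychotic MDD under the
register definition: any F32.3/F33.3 carrier is psychotic) carry no
within-person comorbidity information, so their r_g uses maximum
likelihood on the 3×3 table of pair outcome categories (none / trait 1 /
trait 2 per person).  Each person has two latent liabilities; the observed
category applies the exclusivity rule "psychotic wins": psychotic if l₁ >
z₁ regardless of l₂, otherwise non-psychotic if l₂ > z₂, otherwise none.
The 4-dimensional correlation matrix over (l₁ₐ, l₂ₐ, l₁ᵦ, l₂ᵦ) is

* within person: r_w = r_g·√(a₁²a₂²) + r_e·√(e₁²e₂²), with the
  unique-environment cross-trait correlation r_e unidentifiable for
  exclusive traits and set to 0 by default (a structural assumption,
  configurable);
* cross person, same trait: s·a² + c·c²;
* cross person, cross trait: s·r_g·√(a₁²a₂²).

Thresholds reproduce the observed person-level margins exactly: the
winner's threshold comes directly from its observed frequency, the other
trait's threshold solves P(l₁ ≤ z₁, l₂ > z₂; r_w) = observed margin at
each candidate r_g.  The multinomial log-likelihood over unordered pair
categories is maximised over r_g ∈ (−0.999, 0.999) by bounded Brent search
(tolerance 1e-5); the reported SE is the observed-information value from
the profile curvature, and likelihood-ratio tests against r_g = 0 and
r_g = 1 are provided (the r_g = 1 null is a boundary; the plain chi-square
reference is the default, a 50:50 mixture is available).  Marginal a²
values are fixed two-stage by default; a joint (r_g, a₁², a₂²) Nelder–Mead
fit with tanh/logit reparameterisation and three starts exists behind
`joint_marginals=True`.  For exclusive traits the univariate marginal fit
for the non-winning trait uses its observed indicator, which is very
mildly contaminated by the exclusivity rule (the co-firing probability is
≲1% of the trait margin at the register-like settings), an accepted
approximation of the two-stage design.

### 4-D normal rectangle probabilities

Pair-category probabilities are rectangles of a 4-variate normal.  They
are computed by a deterministic conditioning scheme: Gauss–Legendre
quadrature of person a's bivariate density over its 2-D cell in
probit-transformed coordinates (nodes at truncated-normal quantiles, so
tail cells keep full relative accuracy), with geometrically refined panels
at infinite cell sides where the probit map has a derivative singularity;
the inner factor is the exact conditional bivariate rectangle probability.
Relative accuracy is ~1e-7 on the cells arising here (validated against
exact bivariate reductions, additivity identities, scipy's randomised-QMC
MVN CDF and 10⁷-draw Monte Carlo); the scheme is fully deterministic, and
by construction the 9 (or 16) category probabilities sum to 1 to ~1e-12.
Non-positive-definite candidate correlation matrices during optimisation
are rejected with a likelihood penalty, never an exception.

### Bootstrap and tests between correlations

Confidence intervals are percentile intervals from resampling families
with replacement (families jointly across kinship classes, implemented on
per-family category-count matrices for speed), re-deriving all cross
tables and refitting; reproducible given a seed.  The default replicate
count in the pipeline is 200 (the register-style analysis convention is
1000; the smaller default keeps the smoke pipeline fast and is a
configuration choice).  Equality of two genetic correlations is tested
two-sided on the paired bootstrap distribution of r_g1 − r_g2, with a
(k+1)/(n+1) finite-sample correction.  The coverage of the percentile CI
is verified empirically in the test suite: ~95% over 200 simulation
repetitions at 8,000 full-sibling + 16,000 cousin pairs per repetition and
200 bootstrap replicates — sizes chosen to make the experiment a routine
part of the default test run.

## Familial aggregation

For each kinship class, each unordered pair enters the dataset twice (each
member once as proband, once as relative) and the model is logistic:
relative's outcome ~ proband's exposure + relative's sex + centred birth
year.  Point estimates are logistic ML, identical to GEE with an
independence working correlation; standard errors are cluster-sandwich
with the extended family as the cluster, which absorbs both the
both-orderings duplication and multiple pairs per family.  No small-sample
correction is applied, so with one independent pair per family the
sandwich SE equals the classical Woolf SE exactly (asserted to 1e-8 in the
tests).  Exchangeable working correlations are deliberately not
implemented: independence estimates are consistent and inference rests on
the robust SEs.  Separation and singular designs raise typed errors (the
latter naming the collinear columns).  Bonferroni correction flags
estimates at α / number-of-tests.

## Polygenic-score case–case models

Scores are standardized to mean 0, SD 1 within the analysis sample using
the sample (n−1) SD — the convention chosen here; with register-scale n
the distinction from the population SD is irrelevant.  Per-SD ORs come
from `statsmodels` logistic fits, univariate or joint, adjusted for sex
(male indicator), age and any supplied principal components.  A guard
refuses joint models containing both the all-bipolar score and its
subtype scores, which are near-collinear by construction.  The severe
comparator restricts the reference class to flagged severe non-psychotic
cases.  Cohort estimates pool by fixed-effect inverse-variance
meta-analysis on the log-OR scale; heritabilities and genetic correlations
pool on their own (raw) scale with weights from bootstrap or
delta-method SEs — the scale convention adopted here since fixed-effect
pooling does not prescribe one.

## The synthetic registry

The generator emulates a national-register linkage.  Each extended family
has a grandparent couple, their two full-sib children married to unrelated
spouses, and two resulting sibships (first cousins of each other); with
configurable probability one parent has a second sibship (half siblings).
Additive-genetic values follow Mendelian transmission (child = mid-parent
plus segregation noise of variance 1/2, multivariate across traits with
the generating r_g matrix), which reproduces the classical expected
liability correlations exactly for every kinship without per-family
covariance assembly; shared environment is drawn per sibship (κ-shared
between a parent's two sibships), unique environment per person.
Direct pair-level generators (`simulate_pairs`) draw from the exact joint
liability normal per kinship block, vectorised and chunked, and are what
the large calibration runs use.

Default trait architectures follow the register-style setting: psychotic
MDD (K = 0.2%, h² = 30.17%), non-psychotic MDD (K = 5%, h² = 40%,
mutually exclusive with psychotic MDD, psychotic wins),
schizophrenia/schizoaffective (K = 1%, h² = 70%), bipolar disorder
(K = 2%, h² = 60%), with genetic correlations 0.82 (psychotic ×
non-psychotic), 0.67/0.46 (each × SCZ/SAD), 0.64/0.70 (each × BD) and 0.53
(SCZ/SAD × BD).  C is 0 by default, matching the register finding that C
is indistinguishable from zero.  The pipeline's small smoke configuration
raises prevalences (3% / 15% / 5%) so that a few-thousand-family run still
has concordant pairs in every cell; this is a demonstration setting, not
the register condition.

Diagnosis ages are uniform over an onset window (18–45 years, capped at
follow-up end).  Among MDD cases, comorbid BD, SCZ/SAD and other-psychotic
diagnosis codes are injected directly with configurable
before/after-index probabilities (defaults for the psychotic group:
15.9% / 17.4% / 21.9% converting after the index diagnosis), replacing
liability-driven code assignment for those persons so configured
conversion proportions are exactly recoverable; non-MDD persons' disorder
codes come from their own liability traits.  Treatment codes (ATC N05A
antipsychotics, ECT procedure code) are drawn with subtype-specific
probabilities (73.9%/23.9% and 14.7%/1.9%).  Censoring (death/emigration)
ages are drawn for a 4% minority, exercising the ≥20-years follow-up
filter.  Birth-year windows and the ten-year sibling birth-gap filter
follow the register design; the gap filter applies to sibling pairs only,
not cousins (a deliberate verbatim reading of the design).

Per-person polygenic scores for case–case work come from two mechanisms:
`simulate_prs_casecase` draws standardized scores from a multivariate
normal and assigns the psychotic label through an exact logistic model
(intercept solved so the expected psychotic fraction matches, degenerate
single-class draws regenerated up to a retry cap); the registry generator
instead shifts class-conditional score means by δ = Sβ (Gaussian
discriminant construction), which reproduces the target per-SD ORs
approximately at the moderate effect sizes used.  The calibration targets
use the exact logistic mechanism.

What the generator does not emulate: diagnostic misclassification and
drift across ICD revisions (ICD-8/9 are a configuration hook only),
assortative mating, age-dependent hazards and truncation beyond simple
censoring, sibling-order effects, genotype-level structure (scores are
drawn, not computed from variants), and population stratification.
Passing tests therefore demonstrate estimator correctness under the
stated generating model, not robustness to these real-data features.

## Numerical and degenerate-input conventions

* Bivariate CDF: composite Gauss–Legendre in the arcsine variable, panels
  refined toward |ρ| = 1; exact limits at ρ = ±1.
* Tetrachoric root-finding: Brent on ρ ∈ (−1+1e-12, 1−1e-12), xtol 1e-12;
  out-of-range p₁₁ (rounding) maps to the boundary with a flag.  The
  ρ ↦ p₁₁ map is flat to machine precision at extreme threshold/ρ
  combinations (φ₂ ≈ 0); there no method can invert, and the tests check
  the forward probability instead.
* WLS constrained solve: bounded linear least squares; the a²+c² ≤ 1
  constraint falls back to SLSQP only when violated.
* ML r_g search: bounded Brent, xatol 1e-5; curvature SE step 5e-3.
* Ties in conversion timing (comorbid diagnosis at exactly the index age)
  count as "before" by default — the diagnostic-conversion reading —
  and are configurable.
* Empty margins, single-class outcomes, self-pairings, pedigree cycles,
  non-PSD correlation inputs and zero-variance score columns raise typed
  errors (`ConfigError` exit code 2, `DataError` exit code 3 in the CLI).

## Problem sizes

The calibration script and the acceptance-style tests run the pair models
at 2.5 million full-sibling and 6.3 million cousin pairs — the scale of
the register analyses — which takes seconds per target because pair
simulation is vectorised; the bootstrap-coverage experiment uses 200
repetitions × 200 replicates at 24,000 pairs per repetition, a reduced
design chosen so the whole suite runs in a few minutes.  At prevalence
0.2% even millions of pairs contain only tens of concordant affected
pairs, so single-replicate recoveries of h² and especially of the
familial-aggregation OR carry substantial Monte-Carlo scatter (the h²
estimator's SE is ≈4 percentage points, matching the width of
register-reported confidence intervals); this is a property of the design
being emulated, not of the implementation.
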