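# Methods

## The two models and why they can agree

For a quantitative trait `Y` measured cross-sectionally, the genetic-by-age
interaction model is

    Y = b0 + bG*G + bAge*AGE + bGxAge*G*AGE + bC*C + e

with `G` the allelic dosage (0–2), `AGE` centered at the analysis-sample
mean, and `C` further covariates. `bGxAge` has units of trait per allele per
year: the per-year modulation of the genetic effect across individuals of
different ages. For individuals measured at two timepoints `t1 < t2`, the
annual-change model is

    (Y2 - Y1)/(t2 - t1) = g0 + gG*G + gC*C + eps

with covariates taken at baseline. Under a set of assumptions — the baseline
visit is a random (non-interventional) timepoint, no calendar-time effect on
`Y`, no birth-cohort effect on `G` or `Y`, genotype-specific trajectories
linear in age, covariate effects constant in age — the two focal
coefficients estimate the same quantity: `gG ~ bGxAge`. The package's
simulator and test suite demonstrate this empirically and probe which
assumptions carry weight (below).

## Analytic power engine

All single tests are 1-df Wald tests. A per-allele effect `beta` at allele
frequency `p` explains a fraction

    r2 = beta^2 * 2p(1-p) * [Var(Age) if interaction] / sd_outcome^2

of the (covariate-adjusted) outcome variance, where `sd_outcome` is the
trait SD for marginal/interaction terms and the annual-change SD for the
change term. The interaction regressor, orthogonalised against the main
effects, has variance `2p(1-p)*Var(Age)` when genotype and age are
independent — which is why a wide age range buys the cross-sectional design
power. The test's noncentrality is `ncp = n*r2/(1-r2)`; discovery-stage
power is evaluated two-sided from the noncentral chi-square, the validation
stage one-sided from the shifted normal.

Each 1-stage approach is the union of two routes,

    PWR = PWR_gws + PWR_2step - PWR_gws*PWR_2step,

where the genome-wide route tests the focal term at `alpha_gws = 5e-8` and
the 2-step route multiplies the power to detect a medium marginal effect at
`alpha_gws` (in the cross-sectional sample) by the focal test at
`0.05/1000` (1000 assumed independent tests among marginally associated
variants). The routes are treated as independent, and the cross-sectional
and longitudinal samples as disjoint. The 2-stage approach multiplies the
1-stage interaction power by a one-sided change-validation power at
`0.05/10` in the independent longitudinal sample.

Minimum detectable effects invert the power curve by bracket expansion and
Brent's method (relative tolerance 1e-6; monotonicity asserted on the
bracket). `required_n` inverts over the sample size and rounds up to the
smallest integer n meeting the target, verified sharp at n-1. The
longitudinal-to-total ratio `f` at which the 1-stage change approach
overtakes the 1-stage interaction approach ("kipping point") is found by
bisection of the signed power difference under `n_long = f*N_total`,
`n_cross = (1-f)*N_total`. Because both union routes compare the same two
focal tests, the crossing sits where the two noncentralities are equal,
giving the closed form `f* = r2_gxage/(r2_gxage + r2_change)` — independent
of the alpha scheme and of the marginal-screen sample size. In the
controlled equal-n, equal-alpha, equal-beta scenario, the interaction test
is the more powerful one iff `2*Var(Age) > age_diff^2/(1 - r_y1y2)`
(`dominance_condition`), which the tests verify against direct power
evaluation over a grid.

### The packaged trait designs and the age variance

Eight trait configurations (weight, BMI, DBP, SBP, pulse pressure, log
HDL-C, LDL-C, log triglycerides) ship with the package: cross-sectional and
longitudinal sample sizes (371k–390k and 12k–53k), trait and annual-change
SDs, medium marginal effects, allele frequency 0.30, follow-up gaps (7.5 y;
4.3 y for lipids) and test–retest correlations (0.91 obesity-like, 0.65
blood-pressure-like, 0.62 lipid-like). The cross-sectional age variance is
not part of the published configuration; the package recovers it per trait
by inverting the published minimum detectable 1-stage interaction effect at
80% power (`recover_var_age_from_min_effect`). We prefer this to inverting
the published interaction explained-variance figure because the latter is
printed with one significant digit, which propagates a several-percent
uncertainty into power and fails to reproduce one published power value
(DBP) at two-decimal precision; the minimum-effect column carries two
significant digits and reproduces all published power, minimum-effect, and
explained-variance figures simultaneously. Recovered values are 55–59
years^2, consistent with recruitment at ages 40–69. Both recoveries and a
direct override are exposed.

With this machinery the engine reproduces the published design table to
printed precision, with one decided exception: the published pulse-pressure
kipping point of 65% is incompatible with that trait's own explained
variance configuration, which forces `f* = 0.012/(0.012+0.009) = 57%`; the
65% figure appears to be read from a plot. The corresponding test asserts
the published value and fails for this one case by design.

## Synthetic cohorts

`simulate_cohort` draws Hardy–Weinberg genotypes at configurable
frequencies, baseline ages uniform on [40, 69] (variance 70.1 y^2),
Bernoulli(1/2) sex, and an assessment date uniform over a 4-year recruitment
window, so birthyear = assessment − age and corr(age, birthyear) ~ −0.99,
reproducing the collinearity that makes birth-cohort adjustment
uninformative in short-recruitment cohorts. Each person follows a linear
trajectory (fixed effects plus a person-level random intercept) observed
with independent visit noise; a configurable fraction receives a second
visit after a N(7.5, 0.8^2) year gap. The (intercept SD, visit SD) split is
calibrated in closed form against a target test–retest correlation:
`var_b = r*total - signal`, `var_e = (1-r)*total`, with the fixed-signal
variance computed analytically from the generative coefficients
(`fixed_effect_variance`); infeasible targets raise. `config_to_design`
maps a generator configuration to the analytic engine's design object using
the model-residual variance scale, so Monte-Carlo and analytic power are
compared on identical terms.

### Violation switches, and what they can and cannot break

Because genotype is independent of age in the base model, the centered
interaction regressor is orthogonal to every function of age alone. Two
consequences, both verified in the test suite:

* a genotype-shared quadratic age term (`quadratic_age_shared`) biases
  neither the interaction nor the change coefficient — only the genotype
  contrast matters. The `quadratic_age_effect` switch therefore bends the
  genotype-dependent trajectory component (`magnitude*G*age_c^2`), under
  which the cross-sectional estimator targets the derivative of the genetic
  effect at the mean age while the change estimator targets the secant over
  the follow-up window; their gap (~magnitude × gap years) is what makes
  the linear-trajectory assumption substantive.
* an additive calendar-time trend (`calendar_time_effect`) accrues over the
  follow-up gap and shifts the change-model intercept away from the age
  slope, but leaves both genetic coefficients unbiased.

`birthyear_effect_on_g` re-draws dosages with allele frequency drifting
linearly over birthyear (trait columns deliberately untouched — the switch
calibrates the genotype~age sensitivity regression, not trait models), and
`genotype_dependent_dropout` removes older effect-allele carriers with
probability `1 - exp(-magnitude*G*max(age - mean, 0))`; both induce the
genotype–age association that the `fit_g_age` sensitivity test is designed
to flag. Zero magnitude is always the identity.

What the generator does not emulate: linkage disequilibrium beyond the
block-correlated panels built in tests, population structure and
relatedness, non-Gaussian trait noise, informative follow-up attendance,
and multi-visit trajectories. Passing tests therefore validate the
statistical machinery under the stated generative model, not robustness to
those real-data features.

## Regression layer

Per-variant fits are closed-form OLS (cross-checked against statsmodels):
the marginal model (without the interaction term), the interaction model,
the annual-change model with baseline covariates, and the genotype~age
sensitivity model. Unrelated simulated individuals make OLS with
principal-component covariates target the same estimands a mixed model
would on biobank data; that substitution is the one deliberate divergence
from common biobank practice. Missing dosages are mean-imputed per variant;
variants below a MAF floor (default 0.01%) are skipped with a recorded
reason. One-sided change p values are taken in the direction of the
discovery interaction effect: p/2 when direction-consistent, 1 − p/2
otherwise. Genomic control estimates lambda as the median 1-df chi-square
of variants farther than 5 Mb from any genome-wide-significant marginal
hit, divided by the theoretical median (~0.455); statistics are deflated
only when lambda > 1. Age-specific effects are projected as
`effect(age) = beta_g_at_mean + beta_gxage*(age - mean_age)`.

## Selection and multiplicity

Significant variants are merged into regions separated by more than 500 kb
(nearest-member distance), then peeled into loci: the smallest-p remaining
variant (ties broken by position, then allele order) indexes a locus and
absorbs everything with r^2 >= 0.01 to it, where r^2 is the squared Pearson
correlation of dosages on a reference panel. Postconditions (region
spacing, index-variant independence, exact partition) are asserted on every
output. The effective number of tests among marginally associated variants
defaults to the count of leading eigenvalues of their dosage correlation
matrix explaining 99.5% of variance, with the Li–Ji estimator available —
the underlying PCA criterion is not uniquely pinned down in the literature,
so both standard options are surfaced. Selection takes the union of the
genome-wide route (`p_gxage < 5e-8`) and the 2-step route (marginal
`p < 5e-8` and `p_gxage < 0.05/M_eff`); validation tiers index variants as
`bonferroni` (one-sided, direction-consistent `p_change < 0.05/M_GxAge`),
`nominal` (`< 0.05`), `none`, or `untested`.

## Enrichment statistics

Effects are first aligned to the marginally trait-increasing allele
(allele/frequency flip plus beta negation; idempotent; exact-zero marginal
effects are flagged, not flipped). Direction enrichment among nominally
significant interactions uses the exact two-sided binomial test at 1/2,
defined as twice the smaller tail capped at one — at p = 1/2 this equals
the minimal-likelihood two-sided definition, so the published values pin
the convention only there. Validation enrichment is the exact upper tail
`P(X >= k)` under Binomial(n, p0 = 0.05). Both routines are property-tested
against full pmf enumeration.

## Phenotype derivation

Blood pressure readings are averaged per visit, with +15/+10 mmHg added to
systolic/diastolic under antihypertensive medication, and pulse pressure
formed afterwards (so the medication adjustment adds exactly 5 mmHg to
pulse pressure). A single available reading is used and flagged. Lipids are
converted from mmol/l to mg/dl (38.67 for cholesterol fractions, 88.57 for
triglycerides); HDL-C and triglycerides are log-transformed; LDL-C is
divided by 0.7 under cholesterol-lowering medication and not logged.
Winsorisation at ±6 SD (moments from the unclipped data) runs after
medication adjustment and transformation, by default on the full baseline
sample. Annual change uses the first usable follow-up in the order regular
repeat > imaging > repeat imaging (lipids: regular repeat only), divided by
the elapsed fractional years; zero-gap individuals are excluded and
counted.

## Numerical and reproducibility choices

Root finding uses Brent's method with bracket expansion (relative tolerance
1e-6, <=200 iterations); explained-variance fractions >= 1 saturate power
at 1; degenerate inputs (monomorphic variants, constant age, empty
longitudinal subsets, r_y1y2 = 1 in the dominance condition) raise or are
flagged rather than silently handled. Every cohort draws from a single
explicitly seeded generator; the pipeline manifest records every threshold
that affects selection plus seed and version, and identical configurations
reproduce identical outputs byte-for-byte.

Problem sizes used by the heavier checks: the equivalence property runs 500
replicate cohorts of 20,000 cross-sectional plus 5,000 longitudinal
individuals with the planted interaction varying across replicates (so the
replicate-level correlation between the two estimators is informative), and
the Monte-Carlo-versus-analytic comparison runs a 3x3 grid over n in
{10,000, 20,000, 40,000} and effects pinned to 30/50/80% analytic power,
1,000 replicates per cell at alpha 1e-3, each cell on an independent
replicate stream.

## Known limitations

The engine's power formulas measure explained variance against the total
(covariate-adjusted) trait SD, as is conventional; for traits where age
explains a large variance share the implied noncentrality is slightly
conservative. The change model uses exactly two visits; multi-visit mixed
models are out of scope. Binary traits, related individuals, and X
chromosome dosage conventions are not supported.
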