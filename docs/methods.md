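# Methods

## Cross-trait York regression with a fixed intercept

The comparison of two GWAS' per-variant effects is an errors-in-variables
problem: both coordinates of every point are estimates with known standard
errors, and overlapping samples induce a correlation r between the two
estimators at a variant. Ordinary or weighted least squares of y on x is
biased toward zero under error in x; York's method weights each point by
the variance of its residual given both error terms. Because both traits'
effects are log odds ratios for the same allele and a variant with no
effect in one trait is expected to have none in the other, the intercept is
pinned at zero and the slope is the single free parameter. The estimate
minimizes

S(b) = Σ (β̂_y − b β̂_x)² / v(b), v(b) = σ_y² + b² σ_x² − 2 b r σ_x σ_y.

For |r| < 1 (enforced at input validation), v(b) ≥ σ_y²(1 − r²) > 0 for
every b, so the objective is well defined on the whole line; the code still
guards the division and names the offending variant if a non-positive
variance ever arises.

*Algorithm.* The solver runs York's iterative reweighting specialised to
the through-origin case, started from the weighted-least-squares slope
(weights 1/σ_y²). Iteration stops when the slope moves by less than 1e-10,
with a cap of 100 iterations; if the fixed point fails to converge or the
gradient of S at the result is not numerically zero, a bracketing bounded
1-D minimization of S(b) (Brent) takes over. Either way the reported slope
is checked to be a stationary point of S. There is no randomness anywhere
in the fit. The slope's standard error comes from the curvature of the
objective, se = sqrt(2 / S''(b̂)), with S'' obtained by central differences
of the analytic gradient (step 1e-5·(1+|b̂|)); for fixed weights this
reduces to the familiar (Σ w x²)^(−1/2).

*Heterogeneity.* At the null of one shared linear relationship, each
standardized residual is approximately standard normal, so S at the
solution is approximately χ² with n − 1 degrees of freedom (one estimated
parameter, intercept fixed). The global heterogeneity p-value is the upper
tail. Monte-Carlo calibration on null data (13 points per replicate, the
size of the GDM lead-variant set) puts the empirical rejection rate at
α = 0.05 within [0.03, 0.07] over 2,000 replicates.

*Outliers.* A variant that follows "its own" effect distribution adds one
free parameter, so the improvement in fit from removing it is compared to
χ²(1). The implementation uses exact leave-one-out refits: for variant j
the slope b₋ⱼ is re-estimated on the other n − 1 points and
statⱼ = (β̂_y,j − b₋ⱼ β̂_x,j)² / vⱼ(b₋ⱼ). Raw p-values are Bonferroni-adjusted
across the n tested variants (the package's convention for replication
testing as well), and the model is refit without the flagged variants. A
one-step approximation would be cheaper but was not needed at these problem
sizes (tens of variants). A caveat inherent to leave-one-out scanning: the
remaining n − 1 points still include any *other* gross outlier, so a
sufficiently extreme contaminant at a high-leverage position can inflate
the statistics of genuine points; with lead-variant-scale effects and a
single planted 10-se outlier the scan flags exactly the planted point.

*Degenerate inputs.* A pair at exactly (0, 0) contributes zero to S for
every slope: it is retained, carries no information, and can never be an
outlier. Fits need at least 2 points, scans at least 3.

## Line-model mixture

Each class k is a prior on *true* effects: bivariate normal, mean zero,
covariance Σₖ = [[σ², ρsσ²], [ρsσ², s²σ²]] with slope s, scale σ (the prior
SD of the trait-X effect, in log-OR units) and correlation ρ (det Σ =
s²σ⁴(1−ρ²); ρ → 1 collapses the prior onto the line y = s·x). Convolving
with the Gaussian estimation noise S of a variant gives the observed pair
the marginal law N(0, Σₖ + S) — the marginal likelihood is closed-form, and
membership posteriors follow from Bayes' rule with the fixed prior weights,
computed in log space (log-sum-exp). If every class's log-likelihood
overflows to −∞ the posterior is returned uniform with a warning rather
than NaN.

*EM.* Only slopes are free; scales, correlations and weights are fixed
hyperparameters. The E-step computes membership posteriors; the M-step
maximizes each class's membership-weighted marginal log-likelihood over its
slope by bounded 1-D maximization (slopes confined to [−50, 50]; vertical
lines are not representable in this parameterization). Iteration stops when
the total log marginal likelihood improves by under 1e-8 (default) or after
1000 iterations; the trajectory is checked to be non-decreasing at every
step and the fitted classes are reported sorted by slope, labels preserved.
Initialisation defaults to slopes (1.0, 0.2), the natural starting pair for
a steep/shallow split; EM on well-separated classes converges in a handful
of iterations.

*Model comparison.* The two- vs one-class Bayes factor is the ratio of
maximized mixture marginal likelihoods with slopes plugged in at their EM
optima (no integration over slope uncertainty), reported as log₁₀. This is
the simplest plug-in reading; with 300 simulated two-class variants it is
positive in essentially every replicate.

*Classification accuracy has a ceiling.* Under the two-class generative
model with slopes 1.53/0.25, scale 0.2 and ρ = 0.99, the class priors
overlap near the origin — small-effect variants are genuinely ambiguous, and
even the Bayes-optimal classifier applied to noise-free true effects labels
only ~97% correctly. The 0.95 posterior threshold exists for exactly this
reason: variants below it are reported "unassigned", and among confidently
assigned variants the truth-agreement exceeds 99% in the planted-truth
simulations. Whole-set accuracy claims are therefore not meaningful for
this model and are not made.

## Genetic-correlation tests and meta-analysis

z = (1 − r_g)/se(r_g) with a one-tailed upper normal p tests departure from
perfect correlation; z = r_g/se(r_g) with a two-tailed p tests departure
from zero. The estimates themselves come from external LD-score-regression
tooling and are inputs. Replication pooling is fixed-effects IVW:
β = Σβᵢ/σᵢ² / Σ1/σᵢ², se = (Σ1/σᵢ²)^(−1/2), with a helper for the
Bonferroni convention (p < α / number of loci tested). Note the printed
z for r_g = 0.71, se = 0.06 is 4.833; tail probabilities from rounded
inputs will not reproduce p-values computed from unrounded estimates.

## Phenotyping

The pregnancy window is [delivery − 280 days, delivery + 35 days], both
ends inclusive: "40" weeks of gestation before delivery and 5 weeks after,
at day precision with no time zones. Rules are applied per pregnancy:

- I1: a gestational-diabetes code dated inside the window.
- I2: any diabetes code inside the window (covers vocabularies without a
  GDM-specific code).
- I3: an abnormal blood-glucose marker from the birth registry attached to
  the pregnancy; modeled as a REGISTRY-vocabulary event whose date equals
  the delivery date, since registry linkage carries no independent schema
  here.
- E1: any diabetes code strictly before the window start that falls outside
  *every* pregnancy window of the person (a diabetes code inside an earlier
  pregnancy's window is gestational evidence, not pre-existing disease, and
  does not exclude later pregnancies).
- E2/E3: pancreatic disease (chronic pancreatitis, pancreatic necrosis,
  pancreatic cancer, cystic fibrosis) or an explicit T1D/T2D code strictly
  before the window start, regardless of window membership.

Exclusion wins over inclusion; otherwise any inclusion makes the pregnancy
GDM; otherwise it is unaffected. "Previous" is read as strictly before the
index window's start — events after the window never affect it. Person
status: CASE with ≥ 1 GDM pregnancy, CONTROL with only unaffected
pregnancies, EXCLUDED otherwise; people without deliveries are out of
cohort and raise rather than silently classify. Classification is invariant
to event order and is a partition: every parous person gets exactly one
status.

Code lists are configuration with documented ICD-10/9/8-style prefix
defaults (e.g. O24.4 for GDM, E10/E11 for T1D/T2D); they are matched as
prefixes of dot-stripped uppercase codes and are intended to be replaced by
registry-exact endpoint definitions via YAML. The only invariant enforced
on a code set is that every GDM pattern is covered by an any-diabetes
pattern.

## Summary-statistics harmonization

Variant keys are chr:pos:ref:alt on GRCh38 with 1-based positions. Rows
failing validation (non-positive se, p outside (0, 1], unparsable numbers,
duplicate keys) are dropped with counted reasons; a missing mandatory
column is a hard error. When the second table stores a locus with ref/alt
swapped, the effect sign is flipped into the first table's orientation;
strand-ambiguous (A/T, C/G) variants matching only after a swap are dropped
because the flip cannot be distinguished from a strand difference. The
estimator correlation r is one global scalar per analysis (0 for
non-overlapping GWAS), with a per-variant column override available. How
sample overlap should be estimated is outside scope; r is an input.

## Simulators

The effect simulator draws, per variant, a class by prior weight, a true
effect pair from N(0, Σ_class), uniform standard errors from configured
ranges, and an observed pair with correlated Gaussian estimation noise. Its
defaults are the two-class configuration above with GWAS-scale standard
errors (0.01–0.05). The registry simulator plants inclusion events inside
windows, exclusion events strictly before a person's first window, and
noise events (an unrelated ICD code or an unknown vocabulary), with
deliveries ≥ 400 days apart so windows never overlap; person-level truth is
therefore known by construction without running the classifier. What these
simulators deliberately do not emulate: linkage disequilibrium between
variants, allele-frequency-dependent power, winner's-curse selection of
lead variants, realistic ICD coding frequencies, or miscoded/undated
events. Passing tests show the estimators and rules are correct under their
own assumptions, not that real registry data are this clean.

## Problem sizes and numerical defaults

Test and acceptance runs use the study-scale set sizes: 13 variants for
heterogeneity calibration (2,000 null replicates), 12 + 1 for the planted
outlier, 300 variants for EM recovery and Bayes-factor checks, 500
replicates for standard-error validation, 1,000–2,000 variants or persons
for accuracy/truth checks. York iteration tolerance 1e-10 on the slope, EM
tolerance 1e-8 on the log-likelihood, slope bounds [−50, 50], posterior
assignment threshold 0.95, scan significance 0.05 Bonferroni. All
simulation entry points take explicit seeds and no global random state is
touched.
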