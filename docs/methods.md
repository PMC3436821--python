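# Methods

## Model

One feature in one subject yields a 2×2 table with cells *a* (count before
treatment), *b* (after), and complementary cells *c = t_a − a*,
*d = t_b − b*, where *t_a*, *t_b* are total sample counts.  The observed
fold change is *f = (a/t_a)/(b/t_b)*; the estimand is the true fold change
φ = π_a/π_b of the underlying fractions.

**Technical variation.**  Counts are Poisson with means π_a·t_a and π_b·t_b.
Conditioning on the pair total *s = a + b* gives an exact one-parameter
binomial: *a | s ~ Bin(s, p)* with *p = φ·t_a/(φ·t_a + t_b)*.  For platforms
whose replicate variance deviates from Poisson, the binomial pmf is raised
to a power *v* and renormalized over its support {0, …, s} (the
exponentiated binomial; the exponentiated-Poisson normalizer cancels in the
conditioning and is never computed).  Variance scales roughly as 1/v:
v < 1 over-dispersed, v > 1 under-dispersed, v = 1 exact Poisson.

**Biological variation.**  φ varies between subjects as φ = u/(1−u),
u ~ Beta(α, β) — an inverted-beta random effect.  u = 0.5 (i.e. φ = 1) is
the no-effect point, and α = β makes it the distribution's center of mass.
The marginal likelihood of one table integrates u out; for N subjects the
log likelihoods add.

**Inference.**  The full model maximizes ℓ(α, β); the null maximizes along
α = β.  S = 2(ℓ_full − ℓ_null) is referred to χ² with 1 df; α̂/β̂ is the
common fold-change estimate (the estimator is the shape ratio, not a mean
or median of the random-effect law); a Wald interval for log(α/β) comes
from the observed information in (log α, log β) via the delta method.

## Numerical evaluation of the marginal

The marginal is a 1-D integral over u ∈ (0, 1) with integrand
(conditional pmf) × (beta density).  Three evaluation paths, all in log
space with log-gamma and log-sum-exp throughout:

* **Closed form** (v = 1, t_a = t_b): the beta-binomial pmf
  C(s, a)·B(a+α, b+β)/B(α, β).
* **Gauss–Jacobi** (v = 1, t_a ≠ t_b): after z = 2u − 1 the integrand
  factors into a Jacobi weight (1−z)^(A)(1+z)^(B) times a smooth residual.
  The weight's shape parameters are chosen per table as A = β + b − 1,
  B = α + a − 1, absorbing *all* endpoint powers (beta density and the
  binomial's u^a(1−u)^b) so the residual is the analytic function
  (1 + (r−1)u)^(−s), r = t_a/t_b.  A fixed shape such as (0.5, 0.5) looks
  attractive because one rule would serve every evaluation, but it leaves
  residual exponents α − α₀, β − β₀ in the integrand, which is endpoint-
  singular whenever α or β is small and cannot reach 1e−8 accuracy at any
  practical order; the absorbed form is exact up to the residual, whose
  required polynomial degree grows like √s·|log r|, so the rule order is
  scaled as 32 + 3·√s·|log r| (minimum: the configured order, default 64).
  Nodes and log-scale weights come from an in-package Golub–Welsch
  routine (symmetric tridiagonal eigenproblem); weights are kept as
  logarithms because the total mass 2^(A+B+1)·B(A+1, B+1) overflows double
  precision for the large absorbed exponents the optimizer visits.
* **tanh–sinh** (v ≠ 1): the exponentiated-binomial normalizer varies with
  u and contributes fractional endpoint powers (terms in u^v), which defeat
  polynomial quadrature.  A fixed double-exponential rule (step 1e−3,
  t ∈ [−5, 5], 10,001 nodes) handles arbitrary endpoint exponents
  α, β > 0 and resolves interior posterior bumps down to widths of a few
  1e−3, covering the optimizer box.  The conditional-pmf factor at the
  nodes is independent of (α, β) and is cached per table, so repeated
  likelihood evaluations during optimization cost one log-sum-exp.

Accuracy is enforced by tests: agreement with the closed form to 1e−8,
marginal normalization over the support to 1e−8 across randomized
(α, β ∈ [0.2, 50], v ∈ {0.2, 1, 5}, unequal totals), and agreement with an
independent adaptive integrator.

## Optimization

Both fits run in (log α, log β) inside the box [−10, 10]² (α, β ∈
[4.5e−5, 2.2e4]).  The full fit is multi-start L-BFGS-B — from (1, 1), a
method-of-moments start, the null optimum and a high-concentration start —
with the analytic score: ∂ℓ/∂α = Σ E[log u | data] − N(ψ(α) − ψ(α+β)),
where the posterior expectation is computed with the same quadrature
weights as the likelihood.  The null fit is a 41-point grid scan over log α
refined by bounded scalar minimization.  S is clamped at zero (nested
models).  The score is validated against central finite differences to
1e−4 relative error; the confidence-interval Hessian is a central
difference of the analytic score.

Features with all counts zero on one side push the MLE to the box
boundary; the fit is reported with its `at_bound` flag set and the LRT
p-value retained (conservative).  Features with zero counts everywhere are
flagged `untestable` with p = 1.  Zero-total pairs (a = b = 0) contribute
log-likelihood 0 and are retained, leaving N unchanged.

A consequence of the box worth knowing: for v < 1 the renormalized
exponentiated binomial can over-explain the observed between-pair spread,
so the full-model likelihood increases monotonically along an α + β → ∞
ridge toward its fixed-effect limit.  The box caps the ridge; the reported
S is then within ~0.01 of the supremum (the worked example at v = 0.2
gives S = 5.83, p = 0.016).

## Baselines

Mantel–Haenszel: Cochran–MH chi-square (1 df, no continuity correction) and
the MH pooled risk ratio Σ a_n t_{b,n}/T_n / Σ b_n t_{a,n}/T_n, both via
statsmodels' `StratifiedTable`.  DerSimonian–Laird: per-pair log fold
changes with sampling variance 1/a + 1/b + 1/c + 1/d (0.5 added to all four
cells of any table containing a zero), τ² by the classic moment estimator
clamped at zero (statsmodels `combine_effects`, method "dl"), and a normal
z-test on the precision-weighted mean.  A single stratum reduces DSL to a
fixed-effect Wald test.  Both are cross-checked in the tests against
hand-written textbook formulas.

## Synthetic data

`simulate_ibb_dataset` draws u ~ Beta(α, β), maps it to the binomial
success probability with the study's totals, and draws the before-count
conditionally on a fixed per-pair total (exact finite-support inversion
when v ≠ 1).  This conditional mode reproduces the fitted likelihood
exactly, so parameter recovery is a clean oracle; an unconditional mode
draws both margins as Poisson for end-to-end pipeline tests.  Default study
conditions for calibration experiments: α = β = 8 under the null (between-
pair fold-change spread of roughly ±25%), α/β = 3 for effect features,
N = 5 pairs, pair total s = 100, per-sample totals 1e5.  All generators are
bit-reproducible given (seed, config).

What the generator does *not* emulate: feature-to-feature dependence,
shared normalization artifacts, varying per-pair totals (unless supplied),
or abundance-dependent dispersion across features.  Passing calibration
tests therefore demonstrates the correctness of the test under its own
model, not robustness to real-data violations of it.

The normal-approximation experiment replicates Poisson pairs at an
observed table (2, 8, 30000, 30000), adds 0.5 to all four cells (the same
convention as the DSL correction), and histograms log fold changes at bin
width 0.1.  Modes are counted as local maxima with prominence ≥ 1% of the
tallest bin, plus dominant edge bins.

## Display normalization

`normalize_for_display` scales every column to the mean total and rounds
half-away-from-zero.  It exists only to present counts on a common scale;
inference always uses raw counts and totals.  Totals default to column
sums; an explicit totals file overrides them (a filtered matrix's true
sample totals exceed its column sums).

## Known limitations

* **Small-sample anti-conservativeness.**  The χ²₁ reference for S is
  asymptotic in the number of pairs.  At N = 5 the null rejection rate at
  the 0.05 cutoff is about 0.09–0.10 (mean S ≈ 1.25 rather than 1.0, a
  Bartlett-type inflation); calibration is restored with more pairs
  (≈ 0.068 at N = 15, ≈ 0.040 at N = 50).  The test suite measures this
  honestly; no small-sample correction is applied because the LRT/χ²₁
  construction is the method's definition.
* The per-pair forest intervals use Clopper–Pearson on the conditional
  binomial (a choice; other exact intervals would differ slightly), and
  per-pair weights are proportional to the pair total a + b.
* The common-fold-change point estimator α̂/β̂ is a shape ratio; for highly
  skewed random-effect laws it is neither the mean nor the median of the
  fitted φ distribution.
* Each feature is fit independently; there is no dispersion sharing across
  features, no unpaired-design support, and no normalization beyond
  total-count scaling.
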