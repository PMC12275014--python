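# Methods

This note documents the statistical models implemented in `extremenorm`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical choices that matter.

## Normative stage

Each continuous phenotype y is modeled on a training split as a Bayesian
linear regression on an expanded covariate basis: a clamped cubic B-spline
in age with interior knots at training quantiles (3 by default), a 0/1 sex
indicator, and drop-first one-hot site. The response is standardized and,
optionally, warped by the monotone sinh-arcsinh map

    t = sinh(δ · asinh(y_std) − ε),   δ > 0,

whose two parameters absorb skew (ε) and tail weight (δ). Prior precision
α and noise precision β are set by maximizing the marginal likelihood
(type-II ML), computed in closed form from the SVD of the design matrix;
with warping enabled, (α, β, ε, δ) are optimized jointly on the evidence
plus the warp's log-Jacobian, from three Nelder-Mead starts at
δ ∈ {0.7, 1, 1.5}. This is a deliberately simplified warped-regression
variant: no hierarchical or Gaussian-process extensions, one warp layer,
one global prior precision.

Deviation scores standardize the transformed response by the posterior
predictive distribution, z = (t − Xŵ)/√(1/β + xᵀA⁻¹x), so parameter
uncertainty inflates the predictive SD where the basis is poorly
supported. Held-out metrics: explained variance of the inverse-warped
predictive median; MSLL (mean predictive negative log-likelihood on the
raw scale, Jacobian included, minus a trivial Gaussian fitted to the raw
training response — negative is better than trivial); and the skewness
and excess kurtosis of the held-out z-scores. The QC rule excludes
variables with explained variance < 0, |skew| > 1, or |excess kurtosis|
> 3; these bounds are conventional screening defaults, configurable.

Test ages outside the training range are clamped to the spline boundary
(documented boundary extension); an unseen site label raises an error
naming the label rather than extrapolating silently.

Calibration caveat: the held-out z-mean carries the training-estimation
error coherently across test subjects, so its Monte-Carlo SE is
√(1/n_test + p/n_train), not 1/√n_test; the tests use the inclusive form.

## Univariate tails

GPD cdf/quantile are written with `log1p`/`expm1` so the inverse pair
round-trips to ~1e−15 even at |ξ| near the Gumbel switch; |ξ| < 1e−6
uses the exponential-limit closed forms. Maximum likelihood runs on
(log σ̃, ξ) with ξ bounded to (−0.5, 1] for estimator regularity, from
method-of-moments starts; standard errors are delta-method transforms of
the inverse observed information (central-difference Hessian). Fewer than
30 exceedances warns; zero errors out.

Threshold diagnostics: the mean-residual-life curve (mean excess vs
threshold with normal bands — flat for exponential data, slope
ξ/(1−ξ) under a GPD) and the parameter-stability table, which refits at
each candidate threshold and reports ξ̂ and the threshold-invariant
modified scale σ* = σ̃ − ξk with delta-method 95% bands. The default
candidate grid spans the empirical 0.50–0.995 quantiles in steps of
0.005. Threshold choice itself remains a visual/judgment step; no
automatic selector is provided.

Return levels use x_m = k + (σ̃/ξ)((mζ)^ξ − 1) with ζ the exceedance
rate and the log limit at ξ → 0; m·ζ < 1 is rejected because such levels
lie below the threshold and are not described by the tail model. GEVD
block-maxima fitting uses Nelder-Mead on (μ, log σ, ξ) from
Gumbel-moment starts.

## Multivariate tails

The rank transform F̂ = rank/(n+1) (mid-ranks for ties) keeps F̂ strictly
inside (0,1); the marginal map to the common-tail-index scale is
x = (−log F̂)^(−1/2), the inverse of the Fréchet CDF exp(−x^−2) with
α = 2. Writing the map this way (rather than as the exponent −log F̂
itself) is what makes every margin Fréchet(2), which the second-moment
theory of the TPDM requires. Rows with any missing value are dropped
complete-case with a logged count, since the polar decomposition needs
full vectors.

The radius is the L2 norm — the norm consistent with α = 2 regular
variation — and the radial threshold is the empirical q-quantile of r,
default q = 0.95. Two normalization constants are exposed for the
angular second-moment matrix: `printed` (constant 2; trace ≡ 2 in any
dimension) and `unit` (constant D; diagonal → 1 under unit-scale
Fréchet(2) margins, trace ≡ D). They differ by the positive scalar D/2
only, so eigenvectors, scale proportions, and within-component
contribution rankings are provably identical; `unit` is the default
because it makes the estimator converge to the max-linear oracle B·Bᵀ.

Loadings and contributions come in two conventions: `printed`
(f_l = u_l·λ_l, c_dl = f_dl²/λ_l, summing to λ_l per component) and
`conventional` (f_l = u_l·√λ_l, contributions summing to 1). Eigenvector
signs are fixed by making each vector's largest-magnitude entry positive.
A 1/D average-contribution reference value accompanies ranking outputs.

Per-subject component scores are not uniquely defined by the theory; the
default projects the column-wise log of the pseudo-Fréchet values onto
the eigenbasis (the log maps the positive half-line to the whole real
line), with a raw-projection option; the choice is recorded in output
metadata.

### Finite-threshold bias for tail-independent pairs

For pairs that are independent in the tail, the plain angular estimator
does not return 0 at a fixed radial quantile: conditional on an
exceedance, the non-extreme coordinate contributes
E[ω_i ω_j] ≈ E[X_small]·E[1/r | r > r₀] ~ 1/r₀, a bias that is constant
in n when q is fixed (≈ 0.3 at q = 0.95 for two independent Fréchet(2)
margins) and vanishes only as the threshold grows. Consequently (i)
off-diagonal zeros are recovered only in the regime where the exceedance
fraction shrinks with n, and (ii) "error decreases with n at fixed q"
holds for the variance component but not the bias floor. The tests assert
the correct scaling behavior (bias decreasing in q; mean error decreasing
when the threshold grows with n); one idealized fixed-threshold
independence bound is asserted as stated and fails for this documented
reason.

## Association screen

A phenotype with exactly two distinct non-missing values is tested with
point-biserial correlation (Pearson against the 0/1 coding); all others
with Spearman. p-values use the t approximation
t = r√((n−2)/(1−r²)) (a seeded permutation option exists for small n);
they are floored at 1e−300 before the −log10 transform. Bonferroni
corrects across the full grid m = (#tested phenotypes) × (#components);
phenotypes skipped for being constant or too sparse do not inflate m.
Pairwise-complete observations are used per test. The per-phenotype
aggregate reports the most significant component. No covariate
adjustment is applied to the associations. Comparators: correlation-
matrix PCA (eigenvalues sum to D by construction) and per-subject counts
of deviations beyond ±1.96.

## Synthetic generators

Covariates: age uniform on [40, 80] years, sex Bernoulli(0.53) (1 =
female), three sites uniform. IDPs are a per-variable trend (linear +
mild quadratic in centered age, additive sex effect, additive per-site
intercepts) plus independent Gaussian noise; no scanner physics, no
realistic IDP marginals, no missingness are simulated — passing tests
show estimator correctness under the stated generating model, not
robustness to real acquisition artifacts.

Tail-dependent deviation matrices come from the max-linear construction
X_i = max_k B_ik Z_k with i.i.d. Fréchet(2) factors (inverse-CDF
sampling, Z = (−log U)^(−1/2)). Its angular measure is discrete with
mass ‖B_{:,k}‖² at B_{:,k}/‖B_{:,k}‖, so the true TPDM is exactly B·Bᵀ —
the closed-form oracle used throughout. Pushing each margin through its
exact Fréchet CDF and the standard-normal quantile yields z-score
matrices with N(0,1) margins and unchanged copula, which is what the
rank-based estimation chain must be invariant to.

Behavioral phenotypes: planted continuous columns are
effect·standardized-score + N(0,1); planted binary columns are the
median split of that construct (keeping point-biserial power
analyzable); null columns are independent N(0,1) or fair coin flips.

The bulk-vs-tail mixture plants a ρ = 0.9 Gaussian correlation on one
variable pair and rare joint extreme events (probability 0.045, common
shifted-Fréchet amplitude) on a disjoint pair, so bulk PCA and extreme
PCA must disagree; the tail-event rate is set just below the 0.05 radial
exceedance fraction so the exceedance set is dominated by planted
events.

## Problem sizes and determinism

Default validation sizes: n = 20000 subjects for tail-dependence oracles
(1000 radial exceedances at q = 0.95), 397 excesses × 200 replicates for
GPD coverage, 12000 subjects (1/6 train) for normative calibration, and
60 replicates of a 500-phenotype × 2-component null screen for
family-wise error calibration — sizes at which Monte-Carlo error is well
below the asserted tolerances. All generators take explicit integer
seeds (`numpy.random.default_rng`) and are bitwise reproducible; the
pipeline writes a manifest with SHA-256 checksums of every artifact, and
identical config + seed reproduces identical bytes.

## Known limitations

- The angular measure H itself is never modeled — only its second
  moments (the TPDM), which cannot distinguish tail structures sharing
  second moments.
- The TPDM estimator's finite-threshold bias (above) inflates weak
  off-diagonals at moderate thresholds.
- The warped regression is a single-layer sinh-arcsinh variant; heavy
  multimodality or covariate-dependent noise is out of scope.
- Subject-level extreme-PC scores are a convention, not a derived
  quantity; both exposed options are projections, and conclusions that
  depend on the choice should be checked under both.
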