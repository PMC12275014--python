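# extremenorm

Extreme value statistics for normative-model deviation scores: univariate
peaks-over-threshold tail fitting, multivariate tail dependence via the
tail pairwise dependence matrix (TPDM), "extreme" principal components,
and phenome-style association screening — with a synthetic-data module
whose tail structure is known in closed form, so every estimator in the
chain can be validated against an exact oracle.

## The problem

Normative models regress a biological measure (e.g., an image-derived
phenotype, IDP) on reference covariates — age, sex, acquisition site —
and convert each subject's measurement into a deviation score

    z = (y − μ̂(x)) / σ̂(x),

a standardized residual from the reference cohort. In clinical
neuroscience and epidemiology the scientifically interesting subjects
often live in the *tails* of these deviations, where Gaussian bulk models
are systematically wrong. This package treats the tails with the proper
limiting laws:

**Univariate.** Excesses above a high threshold k converge to the
generalized Pareto distribution (GPD),

    H(y) = 1 − (1 + ξ y / σ̃)^(−1/ξ),   y = z − k > 0,

with shape ξ and scale σ̃ estimated by maximum likelihood, standard errors
from the observed information, and threshold choice supported by
mean-residual-life and parameter-stability diagnostics. Block maxima /
GEVD fitting and return levels are included.

**Multivariate.** Each deviation column is rank-transformed,
F̂ = rank/(n+1), and mapped to pseudo-Fréchet values x = (−log F̂)^(−1/2)
with common tail index α = 2. Rows are written in polar coordinates
x = r·ω (L2 norm) and thresholded at the empirical 95th quantile of the
radius r. The TPDM

    σ̂_ij = (c / n_exc) Σ_{r_n > r₀} ω_ni ω_nj

is the second-moment matrix of the extreme angles — a covariance analogue
for the joint tail. Its eigendecomposition yields extreme principal
components ordered by the tail "scale" they explain, with per-variable
loadings f_l = u_l·λ_l and contributions c_dl = f_dl²/λ_l.

**Association.** Component scores are screened against behavioral
phenotypes with Spearman (continuous) or point-biserial (binary)
correlation and Bonferroni correction across the full phenotype ×
component grid, with a standard correlation-PCA comparator and a
|z| > 1.96 deviation-count comparator.

**Oracle.** The synthetic generator draws max-linear vectors
X_i = max_k B_ik Z_k with Fréchet(2) factors; the true TPDM of this
construction is exactly B·Bᵀ, giving an analytic target for the entire
estimation chain.

## Worked example

```python
import numpy as np
import extremenorm as en

# a known tail-dependent deviation matrix: 3 variables, 2 tail factors
B = np.array([[1.0, 0.0], [0.8, 0.6], [0.0, 1.0]])
spec = en.MaxLinearSpec(B)
z = en.gen_tail_dependent_zscores(20000, spec, seed=1)

# univariate tail of one column, thresholded at its 95th percentile
col = z["var_0001"].to_numpy()
fit = en.fit_gpd_pot(col, np.quantile(col, 0.95))
print(fit.scale, fit.shape)

# multivariate tail dependence and extreme PCA
tpdm, polar, x = en.tpdm_from_zscores(z, quantile=0.95, normalization="unit")
basis = en.extreme_pca(tpdm)
scores = en.project_scores(x, basis, n_components=2)

# screen the component scores against phenotypes (one planted, 50 null)
pheno = en.gen_phenotypes(scores, en.PhenotypeSpec(
    n_null=50, planted=(en.PlantedEffect(component=0, effect=0.3),)), seed=2)
table = en.associate_components(scores, pheno, alpha=0.05)
```

Output:

```
GPD at k=1.6259: scale 0.480 +/- 0.020, shape -0.156 +/- 0.029 (1000 exceedances)
TPDM:
 [[1.016 0.867 0.328]
 [0.867 0.97  0.722]
 [0.328 0.722 1.013]]
oracle B @ B.T:
 [[1.  0.8 0. ]
 [0.8 1.  0.6]
 [0.  0.6 1. ]]
scale proportions: [0.766 0.231 0.003]
          phenotype  component     test  correlation  neg_log10_p  bonferroni_significant
planted_000_cont_c0          0 spearman     0.267712   300.000000                    True
```

The estimated TPDM tracks the oracle B·Bᵀ (the off-diagonal 0.33 where the
oracle is 0 is the expected finite-threshold bias of the angular estimator
for tail-independent pairs; see `docs/methods.md`). The negative GPD shape
says the rank-transformed-then-Gaussianized margins have a short upper
tail at this threshold. The planted phenotype is the only Bonferroni
survivor; its p-value underflows the 1e−300 floor.

The same workflow is available from the shell:

```sh
extremenorm simulate  --n-subjects 5000 --d-idps 6 --output-dir run/
extremenorm normative --covariates run/covariates.csv --idps run/idps.csv --output-dir run/
extremenorm epca      --zscores run/zscores.csv --output-dir run/
extremenorm run-all   --seed 1 --output-dir run_all/   # full pipeline + manifest
```

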