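"""Synthetic data generators with analytically known tail structure.

Every input the pipeline consumes — demographic covariates, continuous
phenotypes (IDPs) with a known mean trend, deviation-score matrices with
planted multivariate tail dependence, and behavioral phenotype tables with
planted associations — can be generated here with full ground truth.

The central device is the max-linear construction

    X_i = max_k  B[i, k] * Z_k,      Z_k i.i.d. Frechet(alpha),

with a nonnegative coefficient matrix ``B``.  For tail index ``alpha = 2``
its angular measure is discrete with mass ``||B[:, k]||_2**2`` at the atom
``B[:, k] / ||B[:, k]||_2``, so the tail pairwise dependence matrix is
exactly ``B @ B.T``.  That closed form is the oracle every downstream
tail-dependence estimator is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MaxLinearSpec",
    "TrendSpec",
    "PhenotypeSpec",
    "PlantedEffect",
    "gen_covariates_and_idps",
    "gen_maxlinear_frechet",
    "gen_tail_dependent_zscores",
    "gen_phenotypes",
    "gen_bulk_tail_mixture",
    "default_trend_specs",
]

GENERATOR_VERSION = "1"

DEFAULT_AGE_RANGE = (40.0, 80.0)
DEFAULT_FEMALE_FRACTION = 0.53
DEFAULT_SITES = ("site_a", "site_b", "site_c")


@dataclass(frozen=True)
class MaxLinearSpec:
    """Coefficient matrix and tail index of a max-linear random vector.

    ``coefficient_matrix`` is D x K with nonnegative entries and no all-zero
    row; ``tail_index`` must be 2 for the closed-form TPDM oracle
    ``B @ B.T`` to hold.
    """

    coefficient_matrix: np.ndarray
    tail_index: float = 2.0

    def __post_init__(self) -> None:
        B = np.asarray(self.coefficient_matrix, dtype=float)
        if B.ndim != 2:
            raise ValueError("coefficient_matrix must be 2-dimensional")
        if not np.all(np.isfinite(B)):
            raise ValueError("coefficient_matrix entries must be finite")
        if np.any(B < 0):
            raise ValueError("coefficient_matrix entries must be nonnegative")
        if np.any(B.sum(axis=1) == 0):
            raise ValueError("coefficient_matrix must have no all-zero row")
        if self.tail_index <= 0:
            raise ValueError("tail_index must be positive")
        object.__setattr__(self, "coefficient_matrix", B)

    @property
    def n_variables(self) -> int:
        return self.coefficient_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coefficient_matrix.shape[1]

    def oracle_tpdm(self) -> np.ndarray:
        """True TPDM of the construction (requires tail_index == 2)."""
        if self.tail_index != 2:
            raise ValueError("the closed-form TPDM oracle requires tail_index = 2")
        B = self.coefficient_matrix
        return B @ B.T

    def marginal_scales(self) -> np.ndarray:
        """Frechet scale of each margin: (sum_k B[i,k]^alpha)^(1/alpha)."""
        B = self.coefficient_matrix
        a = self.tail_index
        return (B**a).sum(axis=1) ** (1.0 / a)


@dataclass(frozen=True)
class TrendSpec:
    """Mean function of one continuous phenotype given the covariates.

    mean = intercept + age_slope*(age-60) + age_curv*(age-60)^2
           + sex_effect*female + site_effects[site]
    """

    intercept: float = 0.0
    age_slope: float = 0.0
    age_curv: float = 0.0
    sex_effect: float = 0.0
    site_effects: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        vals = [self.intercept, self.age_slope, self.age_curv, self.sex_effect,
                *self.site_effects]
        if not np.all(np.isfinite(vals)):
            raise ValueError("trend parameters must be finite")

    def evaluate(self, age: np.ndarray, sex: np.ndarray, site_code: np.ndarray) -> np.ndarray:
        a = np.asarray(age, dtype=float) - 60.0
        site_fx = np.asarray(self.site_effects, dtype=float)[np.asarray(site_code)]
        return (self.intercept + self.age_slope * a + self.age_curv * a**2
                + self.sex_effect * np.asarray(sex, dtype=float) + site_fx)


@dataclass(frozen=True)
class PlantedEffect:
    """One phenotype built from a component score: corr strength + coding."""

    component: int
    effect: float
    binary: bool = False


@dataclass(frozen=True)
class PhenotypeSpec:
    n_null: int = 0
    planted: tuple[PlantedEffect, ...] = field(default_factory=tuple)
    null_binary: bool = False

    def __post_init__(self) -> None:
        if self.n_null < 0:
            raise ValueError("n_null must be nonnegative")
        for p in self.planted:
            if not np.isfinite(p.effect):
                raise ValueError("planted effect sizes must be finite")
            if p.component < 0:
                raise ValueError("planted component indices must be nonnegative")


def default_trend_specs(d_idps: int, seed: int | np.random.Generator = 0,
                        n_sites: int = len(DEFAULT_SITES)) -> list[TrendSpec]:
    """Draw a plausible linear-in-age trend per variable, reproducibly."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(d_idps):
        specs.append(TrendSpec(
            intercept=float(rng.normal(0.0, 1.0)),
            age_slope=float(rng.normal(0.0, 0.05)),
            age_curv=float(rng.normal(0.0, 0.001)),
            sex_effect=float(rng.normal(0.0, 0.5)),
            site_effects=tuple(rng.normal(0.0, 0.3, size=n_sites)),
        ))
    return specs


def gen_covariates_and_idps(
    n_subjects: int,
    d_idps: int,
    trend_specs: list[TrendSpec] | None = None,
    noise_sd: float | np.ndarray = 1.0,
    seed: int = 0,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    female_fraction: float = DEFAULT_FEMALE_FRACTION,
    sites: tuple[str, ...] = DEFAULT_SITES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a covariate table and a subject-by-variable phenotype matrix.

    Ages are uniform on ``age_range`` (default 40-80 years), sex is Bernoulli
    with the configured female fraction (default 0.53, coded 1 = female), and
    site is uniform over the site labels.  Each phenotype is its trend
    evaluated at the covariates plus independent Gaussian noise.

    Returns ``(covariates, idps)``; both carry ``subject_id`` as the first
    column and share row order.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    rng = np.random.default_rng(seed)
    if trend_specs is None:
        trend_specs = default_trend_specs(d_idps, rng.integers(2**31), len(sites))
    if len(trend_specs) != d_idps:
        raise ValueError("need one TrendSpec per variable")
    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (d_idps,))
    if np.any(noise < 0):
        raise ValueError("noise_sd must be nonnegative")

    age = rng.uniform(*age_range, size=n_subjects)
    sex = (rng.random(n_subjects) < female_fraction).astype(int)
    site_code = rng.integers(len(sites), size=n_subjects)
    cov = pd.DataFrame({
        "subject_id": [f"sub-{i:06d}" for i in range(n_subjects)],
        "age": age,
        "sex": sex,
        "site": [sites[c] for c in site_code],
    })

    Y = np.empty((n_subjects, d_idps))
    for j, spec in enumerate(trend_specs):
        mu = spec.evaluate(age, sex, site_code)
        Y[:, j] = mu + (rng.standard_normal(n_subjects) * noise[j] if noise[j] > 0 else 0.0)
    idps = pd.DataFrame(Y, columns=[f"idp_{j:04d}" for j in range(d_idps)])
    idps.insert(0, "subject_id", cov["subject_id"])
    return cov, idps


def _frechet_sample(rng: np.random.Generator, size, alpha: float) -> np.ndarray:
    # inverse-CDF draw: U uniform, Z = (-log U)^(-1/alpha) has CDF exp(-z^-alpha)
    u = rng.random(size)
    return (-np.log(u)) ** (-1.0 / alpha)


def gen_maxlinear_frechet(n_subjects: int, spec: MaxLinearSpec, seed: int = 0) -> np.ndarray:
    """Draw ``n_subjects`` rows of the max-linear vector X_i = max_k B[i,k] Z_k.

    Margins are Frechet(alpha) with scale ``(sum_k B[i,k]^alpha)^(1/alpha)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)
    Z = _frechet_sample(rng, (n_subjects, spec.n_factors), spec.tail_index)
    # row-wise max over factors of B[i,k] * Z[n,k]
    return np.max(Z[:, None, :] * spec.coefficient_matrix[None, :, :], axis=2)


def gen_tail_dependent_zscores(n_subjects: int, spec: MaxLinearSpec, seed: int = 0) -> pd.DataFrame:
    """Deviation-score matrix with standard-normal margins and known tail copula.

    The max-linear draw is pushed through its exact Frechet marginal CDF to a
    uniform and then through the standard-normal quantile function.  Margins
    become exactly N(0, 1) while the copula — and therefore the TPDM — of the
    max-linear construction is preserved (the map is strictly monotone).
    """
    if spec.tail_index != 2:
        raise ValueError("gen_tail_dependent_zscores requires tail_index = 2")
    X = gen_maxlinear_frechet(n_subjects, spec, seed)
    scales = spec.marginal_scales()
    # Frechet(2, scale s) CDF: exp(-(x/s)^-2)
    U = np.exp(-((X / scales[None, :]) ** -2.0))
    Z = stats.norm.ppf(U)
    df = pd.DataFrame(Z, columns=[f"var_{j:04d}" for j in range(spec.n_variables)])
    df.insert(0, "subject_id", [f"sub-{i:06d}" for i in range(n_subjects)])
    return df


def gen_phenotypes(scores: np.ndarray, spec: PhenotypeSpec, seed: int = 0) -> pd.DataFrame:
    """Behavioral phenotype table: planted associations plus pure-null columns.

    Planted continuous phenotypes are ``effect * standardized_score + N(0,1)``
    noise; planted binary phenotypes are the median split of that construct.
    Null phenotypes are independent standard normal (or fair coin flips).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.size == 0:
        raise ValueError("scores must be a non-empty 2-d array")
    n, n_comp = scores.shape
    for p in spec.planted:
        if p.component >= n_comp:
            raise ValueError(f"planted component {p.component} out of range (scores have {n_comp})")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for i, p in enumerate(spec.planted):
        s = scores[:, p.component]
        s = (s - s.mean()) / s.std()
        construct = p.effect * s + rng.standard_normal(n)
        if p.binary:
            cols[f"planted_{i:03d}_bin_c{p.component}"] = (construct > np.median(construct)).astype(int)
        else:
            cols[f"planted_{i:03d}_cont_c{p.component}"] = construct
    for i in range(spec.n_null):
        if spec.null_binary:
            cols[f"null_{i:04d}"] = rng.integers(0, 2, size=n)
        else:
            cols[f"null_{i:04d}"] = rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"sub-{i:06d}" for i in range(n)])
    return df


def gen_bulk_tail_mixture(
    n_subjects: int,
    bulk_pair: tuple[int, int] = (0, 1),
    tail_pair: tuple[int, int] = (2, 3),
    d: int = 4,
    bulk_rho: float = 0.9,
    tail_prob: float = 0.045,
    tail_shift: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deviation matrix whose bulk correlation and tail dependence disagree.

    Most rows are Gaussian with a strong correlation planted on ``bulk_pair``
    and everything else independent.  A small fraction of rows carry a joint
    extreme event on ``tail_pair``: both coordinates are shifted far into the
    upper tail by a common heavy-tailed amplitude.  Bulk PCA is therefore
    dominated by ``bulk_pair`` while the tail dependence — hence the leading
    extreme eigenvector — concentrates on ``tail_pair``.
    """
    if len({*bulk_pair, *tail_pair}) != 4:
        raise ValueError("bulk_pair and tail_pair must be four distinct column indices")
    if not 0 < tail_prob < 0.5:
        raise ValueError("tail_prob must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_subjects, d))
    i, j = bulk_pair
    Z[:, j] = bulk_rho * Z[:, i] + np.sqrt(1 - bulk_rho**2) * Z[:, j]
    is_tail = rng.random(n_subjects) < tail_prob
    amp = tail_shift + _frechet_sample(rng, int(is_tail.sum()), 2.0)
    for c in tail_pair:
        Z[is_tail, c] = amp + 0.1 * rng.standard_normal(int(is_tail.sum()))
    df = pd.DataFrame(Z, columns=[f"var_{c:04d}" for c in range(d)])
    df.insert(0, "subject_id", [f"sub-{i:06d}" for i in range(n_subjects)])
    return df
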