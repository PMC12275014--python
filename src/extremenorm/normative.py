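"""Normative modeling: reference-cohort regression and deviation scores.

Each continuous phenotype is regressed on demographic covariates (a cubic
B-spline in age with knots at training quantiles, a sex indicator, one-hot
site) with a Bayesian linear model.  Prior and noise precisions are set by
maximizing the marginal likelihood (type-II ML).  An optional monotone
sinh-arcsinh warp of the response,

    t = sinh(delta * asinh((y - m)/s) - epsilon),

is estimated jointly by maximum likelihood so that skewed responses are
Gaussianized before the regression; the Jacobian of the warp enters the
likelihood.  Deviation ("z") scores standardize each held-out response by
the posterior predictive distribution:

    z = (t - predictive mean) / predictive SD,

with predictive variance = noise variance + basis-dependent posterior
weight uncertainty.  Under the generating model, held-out z-scores are
standard normal; heavy skew or kurtosis in them flags model misfit, which
drives the configurable QC exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "NormativeConfig",
    "NormativeModelFit",
    "FitMetrics",
    "fit_normative",
    "compute_zscores",
    "evaluate_normative",
    "split_train_test",
    "fit_zscore_matrix",
    "qc_pass",
]


@dataclass(frozen=True)
class NormativeConfig:
    """Basis and warp options for one normative fit."""

    warp: bool = False
    n_age_knots: int = 3          # interior knots, placed at training quantiles
    spline_degree: int = 3
    use_sex: bool = True
    use_site: bool = True


@dataclass(frozen=True)
class BasisSpec:
    """Frozen description of the covariate expansion learned at fit time."""

    age_knots: tuple[float, ...]      # full clamped knot vector
    age_range: tuple[float, float]
    spline_degree: int
    sites: tuple[str, ...]            # first entry is the dropped baseline
    use_sex: bool
    use_site: bool

    @property
    def n_columns(self) -> int:
        n_spline = len(self.age_knots) - self.spline_degree - 1
        return n_spline + int(self.use_sex) + (len(self.sites) - 1 if self.use_site else 0)


def _make_basis_spec(covariates: pd.DataFrame, config: NormativeConfig) -> BasisSpec:
    age = covariates["age"].to_numpy(dtype=float)
    lo, hi = float(age.min()), float(age.max())
    if hi <= lo:
        raise ValueError("age has no spread; cannot build a spline basis")
    k = config.spline_degree
    qs = np.linspace(0, 1, config.n_age_knots + 2)[1:-1]
    interior = np.quantile(age, qs)
    knots = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    sites: tuple[str, ...] = ()
    if config.use_site:
        if "site" not in covariates.columns:
            raise ValueError("covariates lack a 'site' column but use_site=True")
        sites = tuple(sorted(map(str, covariates["site"].unique())))
    return BasisSpec(age_knots=tuple(knots), age_range=(lo, hi),
                     spline_degree=k, sites=sites,
                     use_sex=config.use_sex, use_site=config.use_site)


def _design_matrix(covariates: pd.DataFrame, spec: BasisSpec) -> np.ndarray:
    age = covariates["age"].to_numpy(dtype=float)
    lo, hi = spec.age_range
    age = np.clip(age, lo, hi)  # boundary extension for out-of-range test ages
    t = np.asarray(spec.age_knots)
    X = BSpline.design_matrix(age, t, spec.spline_degree).toarray()
    parts = [X]
    if spec.use_sex:
        parts.append(covariates["sex"].to_numpy(dtype=float)[:, None])
    if spec.use_site:
        site = covariates["site"].astype(str).to_numpy()
        unseen = sorted(set(site) - set(spec.sites))
        if unseen:
            raise ValueError(f"unseen site label(s): {', '.join(unseen)}")
        for s in spec.sites[1:]:   # drop-first coding
            parts.append((site == s).astype(float)[:, None])
    return np.hstack(parts)


# ----------------------------------------------------------------- warp layer

def _warp(y_std: np.ndarray, eps: float, delta: float) -> np.ndarray:
    return np.sinh(delta * np.arcsinh(y_std) - eps)


def _warp_inverse(t: np.ndarray, eps: float, delta: float) -> np.ndarray:
    return np.sinh((np.arcsinh(t) + eps) / delta)


def _warp_logderiv_std(y_std: np.ndarray, eps: float, delta: float) -> np.ndarray:
    # d/dy_std sinh(delta*asinh(y_std) - eps)
    u = delta * np.arcsinh(y_std) - eps
    return np.log(delta) + np.log(np.cosh(u)) - 0.5 * np.log1p(y_std**2)


# ------------------------------------------------------------------- evidence

def _log_evidence(log_alpha: float, log_beta: float, s2: np.ndarray,
                  Vt_Xty: np.ndarray, yty: float, n: int, p: int) -> float:
    """Bayesian linear model log marginal likelihood via the SVD of X.

    ``s2`` are squared singular values, ``Vt_Xty = diag(s) U^T t`` in the
    rotated basis, ``yty = t^T t``.
    """
    alpha, beta = np.exp(log_alpha), np.exp(log_beta)
    d = alpha + beta * s2                      # eigenvalues of A in rotated basis
    m_rot = beta * Vt_Xty / d                  # posterior mean, rotated
    # E(m) = beta/2 ||t - Xm||^2 + alpha/2 ||m||^2
    fit_term = yty - 2 * m_rot @ Vt_Xty + (m_rot**2 * s2).sum()
    E = beta / 2 * fit_term + alpha / 2 * (m_rot**2).sum()
    log_det_A = np.log(d).sum() + (p - s2.size) * log_alpha
    return (p / 2 * log_alpha + n / 2 * log_beta - E
            - 0.5 * log_det_A - n / 2 * np.log(2 * np.pi))


@dataclass(frozen=True)
class NormativeModelFit:
    basis_spec: BasisSpec
    weights: np.ndarray = field(repr=False)
    weight_cov: np.ndarray = field(repr=False)      # posterior covariance A^-1
    noise_variance: float = 1.0
    prior_precision: float = 1.0
    warp_params: tuple[float, float] | None = None  # (epsilon, delta)
    y_center: float = 0.0
    y_scale: float = 1.0
    train_y_mean: float = 0.0                        # raw-scale training summary
    train_y_var: float = 1.0
    log_evidence: float = np.nan
    basis_condition: float = np.nan

    def transform_response(self, y: np.ndarray) -> np.ndarray:
        """Standardize and (optionally) warp a raw response vector."""
        y_std = (np.asarray(y, dtype=float) - self.y_center) / self.y_scale
        if self.warp_params is None:
            return y_std
        return _warp(y_std, *self.warp_params)

    def inverse_transform(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.warp_params is not None:
            t = _warp_inverse(t, *self.warp_params)
        return t * self.y_scale + self.y_center

    def response_log_jacobian(self, y: np.ndarray) -> np.ndarray:
        """log |dt/dy| of the full response transform at raw y."""
        y_std = (np.asarray(y, dtype=float) - self.y_center) / self.y_scale
        out = np.full_like(y_std, -np.log(self.y_scale))
        if self.warp_params is not None:
            out = out + _warp_logderiv_std(y_std, *self.warp_params)
        return out

    def predict(self, covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Posterior predictive mean and SD in the transformed space."""
        X = _design_matrix(covariates, self.basis_spec)
        mean = X @ self.weights
        var = self.noise_variance + np.einsum("ij,jk,ik->i", X, self.weight_cov, X)
        return mean, np.sqrt(var)


@dataclass(frozen=True)
class FitMetrics:
    explained_variance: float
    msll: float
    skewness: float
    kurtosis: float          # excess

    def to_dict(self) -> dict:
        return {"explained_variance": self.explained_variance, "msll": self.msll,
                "skewness": self.skewness, "kurtosis": self.kurtosis}


def fit_normative(y: np.ndarray, covariates: pd.DataFrame,
                  config: NormativeConfig | None = None) -> NormativeModelFit:
    """Fit one normative model by marginal-likelihood maximization.

    With ``config.warp`` the sinh-arcsinh parameters are optimized jointly
    with the precisions (multi-start Nelder-Mead on the penalized evidence,
    which includes the warp Jacobian).
    """
    config = config or NormativeConfig()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; normative fit is degenerate")
    if len(y) != len(covariates):
        raise ValueError("response and covariates must have equal length")

    spec = _make_basis_spec(covariates, config)
    X = _design_matrix(covariates, spec)
    n, p = X.shape
    if n < 10 * p:
        warnings.warn(f"only {n} rows for {p} basis columns; "
                      "fewer than 10 rows per column", stacklevel=2)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    cond = s[0] / s[-1] if s[-1] > 0 else np.inf
    if cond > 1e10:
        warnings.warn(f"basis is near rank-deficient (condition {cond:.2e})",
                      stacklevel=2)
    s2 = s**2

    y_center, y_scale = float(y.mean()), float(y.std())

    def neg_obj(theta: np.ndarray) -> float:
        if config.warp:
            log_alpha, log_beta, eps, log_delta = theta
            delta = np.exp(log_delta)
            y_std = (y - y_center) / y_scale
            t = _warp(y_std, eps, delta)
            jac = _warp_logderiv_std(y_std, eps, delta).sum()
        else:
            log_alpha, log_beta = theta
            t = (y - y_center) / y_scale
            jac = 0.0
        if not np.all(np.isfinite(t)):
            return np.inf
        Ut = U.T @ t
        ev = _log_evidence(log_alpha, log_beta, s2, s * Ut, float(t @ t), n, p)
        return -(ev + jac)

    if config.warp:
        starts = [np.array([0.0, 0.0, 0.0, np.log(d0)]) for d0 in (0.7, 1.0, 1.5)]
        best = None
        for x0 in starts:
            res = optimize.minimize(neg_obj, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8,
                                             "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        log_alpha, log_beta, eps, log_delta = best.x
        warp_params = (float(eps), float(np.exp(log_delta)))
        t = _warp((y - y_center) / y_scale, *warp_params)
        log_ev = -best.fun
    else:
        res = optimize.minimize(neg_obj, np.array([0.0, 0.0]), method="L-BFGS-B")
        log_alpha, log_beta = res.x
        warp_params = None
        t = (y - y_center) / y_scale
        log_ev = -res.fun

    alpha, beta = np.exp(log_alpha), np.exp(log_beta)
    d = alpha + beta * s2
    w = Vt.T @ (beta * s * (U.T @ t) / d)
    weight_cov = (Vt.T / d) @ Vt  # A^-1
    return NormativeModelFit(
        basis_spec=spec, weights=w, weight_cov=weight_cov,
        noise_variance=float(1.0 / beta), prior_precision=float(alpha),
        warp_params=warp_params, y_center=y_center, y_scale=y_scale,
        train_y_mean=float(y.mean()), train_y_var=float(y.var(ddof=1)),
        log_evidence=float(log_ev), basis_condition=float(cond),
    )


def compute_zscores(fit: NormativeModelFit, y: np.ndarray,
                    covariates: pd.DataFrame) -> np.ndarray:
    """Deviation scores: transformed response standardized by the predictive
    distribution, one per subject."""
    mean, sd = fit.predict(covariates)
    t = fit.transform_response(np.asarray(y, dtype=float))
    return (t - mean) / sd


def evaluate_normative(fit: NormativeModelFit, y_test: np.ndarray,
                       covariates_test: pd.DataFrame) -> FitMetrics:
    """Held-out fit metrics: explained variance, MSLL, z-score shape.

    MSLL is the mean predictive negative log-likelihood (raw response scale,
    warp Jacobian included) minus that of a trivial Gaussian with the
    training response's mean and variance; negative values beat the trivial
    model.  Skewness and excess kurtosis are those of the held-out z-scores.
    """
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size < 3:
        raise ValueError("need at least 3 test rows to evaluate")
    mean, sd = fit.predict(covariates_test)
    t = fit.transform_response(y_test)
    z = (t - mean) / sd

    y_hat = fit.inverse_transform(mean)
    denom = y_test.var()
    ev = 1.0 - np.mean((y_test - y_hat)**2) / denom if denom > 0 else np.nan

    nll_model = (0.5 * np.log(2 * np.pi * sd**2) + (t - mean)**2 / (2 * sd**2)
                 - fit.response_log_jacobian(y_test))
    v0 = fit.train_y_var
    nll_trivial = 0.5 * np.log(2 * np.pi * v0) + (y_test - fit.train_y_mean)**2 / (2 * v0)
    msll = float(np.mean(nll_model - nll_trivial))

    return FitMetrics(explained_variance=float(ev), msll=msll,
                      skewness=float(stats.skew(z)),
                      kurtosis=float(stats.kurtosis(z)))


def qc_pass(metrics: FitMetrics, min_explained_variance: float = 0.0,
            max_abs_skew: float = 1.0, max_abs_kurtosis: float = 3.0) -> bool:
    """Default variable-exclusion rule for poorly fitted phenotypes."""
    return (metrics.explained_variance >= min_explained_variance
            and abs(metrics.skewness) <= max_abs_skew
            and abs(metrics.kurtosis) <= max_abs_kurtosis)


def split_train_test(n: int, train_fraction: float = 0.1,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint train/test row indices."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(1, int(round(train_fraction * n)))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def fit_zscore_matrix(
    covariates: pd.DataFrame,
    idps: pd.DataFrame,
    config: NormativeConfig | None = None,
    train_fraction: float = 0.1,
    seed: int = 0,
    qc: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, NormativeModelFit]]:
    """Fit every phenotype column and assemble the held-out z-score matrix.

    Returns ``(zscores, metrics, fits)``: z-scores for the test split (with
    ``subject_id``), per-variable fit metrics, and the fitted models.  With
    ``qc=True``, variables failing :func:`qc_pass` are dropped from the
    z-score matrix (their metrics rows record ``qc_pass = False``).
    """
    cols = [c for c in idps.columns if c != "subject_id"]
    tr, te = split_train_test(len(covariates), train_fraction, seed)
    cov_tr, cov_te = covariates.iloc[tr], covariates.iloc[te]
    z_cols: dict[str, np.ndarray] = {}
    metrics_rows = []
    fits: dict[str, NormativeModelFit] = {}
    for c in cols:
        y = idps[c].to_numpy(dtype=float)
        fit = fit_normative(y[tr], cov_tr, config)
        m = evaluate_normative(fit, y[te], cov_te)
        ok = qc_pass(m)
        metrics_rows.append({"variable": c, **m.to_dict(), "qc_pass": ok})
        fits[c] = fit
        if not qc or ok:
            z_cols[c] = compute_zscores(fit, y[te], cov_te)
    z = pd.DataFrame(z_cols)
    z.insert(0, "subject_id", covariates["subject_id"].iloc[te].to_numpy())
    return z, pd.DataFrame(metrics_rows), fits
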