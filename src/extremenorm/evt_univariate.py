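"""Univariate extreme value statistics for deviation scores.

Peaks-over-threshold fitting of the generalized Pareto distribution (GPD),
block-maxima fitting of the generalized extreme value distribution (GEVD),
threshold-selection diagnostics (mean residual life and parameter stability),
and return levels.

The GPD models excesses Y = Z - k above a high threshold k:

    H(y) = 1 - (1 + xi * y / sigma)^(-1/xi),      sigma > 0,

with the exponential limit 1 - exp(-y/sigma) as xi -> 0.  Shape xi > 0 means
a heavy (Pareto-like) tail, xi = 0 exponential, xi < 0 a finite upper
endpoint at k - sigma/xi.  Fitting is by maximum likelihood over
(log sigma, xi); standard errors come from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GPDFit",
    "GEVDParams",
    "gpd_cdf",
    "gpd_quantile",
    "fit_gpd_pot",
    "mean_residual_life",
    "parameter_stability",
    "return_level",
    "fit_gevd_block_maxima",
    "default_threshold_grid",
]

#: below this |xi| the exponential / Gumbel limiting forms are used
XI_EPS = 1e-6


# ----------------------------------------------------------------- closed forms

def gpd_cdf(y, scale: float, shape: float):
    """GPD distribution function of excesses y >= 0.

    Values beyond the upper endpoint (shape < 0) map to probability 1;
    negative excesses raise.
    """
    y = np.asarray(y, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if np.any(y < 0):
        raise ValueError("excesses must be nonnegative")
    if abs(shape) < XI_EPS:
        out = -np.expm1(-y / scale)
    else:
        arg = 1.0 + shape * y / scale
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(arg > 0,
                           -np.expm1(-np.log1p(shape * y / scale) / shape), 1.0)
    return out if out.ndim else float(out)


def gpd_quantile(p, scale: float, shape: float):
    """Inverse of :func:`gpd_cdf` on probabilities in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if abs(shape) < XI_EPS:
        out = -scale * np.log1p(-p)
    else:
        out = scale / shape * np.expm1(-shape * np.log1p(-p))
    return out if out.ndim else float(out)


def _gpd_nll(log_scale: float, shape: float, y: np.ndarray) -> float:
    scale = np.exp(log_scale)
    n = y.size
    if abs(shape) < XI_EPS:
        return n * log_scale + y.sum() / scale
    arg = 1.0 + shape * y / scale
    if np.any(arg <= 0):
        return 1e10  # outside the support; finite so gradient steps stay usable
    return n * log_scale + (1.0 + 1.0 / shape) * np.log(arg).sum()


def _moment_start(y: np.ndarray) -> tuple[float, float]:
    """Method-of-moments GPD start values (clamped into the valid region)."""
    m, v = y.mean(), y.var()
    if v <= 0:
        return float(np.log(max(m, 1e-8))), 0.0
    xi0 = 0.5 * (1.0 - m**2 / v)
    xi0 = float(np.clip(xi0, -0.4, 0.4))
    sigma0 = max(m * (1.0 - xi0), 1e-8)
    return float(np.log(sigma0)), xi0


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with steps relative to |x|."""
    x = np.asarray(x, dtype=float)
    k = x.size
    steps = h * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


@dataclass(frozen=True)
class GPDFit:
    """Maximum-likelihood GPD fit to threshold excesses.

    ``scale`` is the threshold-dependent scale (sigma-tilde); ``shape`` the
    tail index xi; ``exceedance_rate`` the empirical P(Z > threshold).
    """

    threshold: float
    scale: float
    shape: float
    n_exceedances: int
    n_total: int
    scale_se: float
    shape_se: float
    cov: np.ndarray = field(repr=False)
    loglik: float = np.nan

    @property
    def exceedance_rate(self) -> float:
        return self.n_exceedances / self.n_total

    @property
    def modified_scale(self) -> float:
        """Threshold-invariant reparameterization sigma* = scale - shape*k."""
        return self.scale - self.shape * self.threshold

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "scale": self.scale, "shape": self.shape,
            "scale_se": self.scale_se, "shape_se": self.shape_se,
            "n_exceedances": self.n_exceedances, "n_total": self.n_total,
            "exceedance_rate": self.exceedance_rate, "loglik": self.loglik,
        }


def fit_gpd_pot(
    z: np.ndarray,
    threshold: float,
    min_exceedances: int = 30,
    shape_bounds: tuple[float, float] = (-0.5, 1.0),
) -> GPDFit:
    """Fit a GPD to the excesses of ``z`` above ``threshold`` by ML.

    The optimizer works on (log scale, shape) with the shape constrained to
    ``shape_bounds`` for estimator regularity, starting from method-of-moments
    values.  Standard errors are delta-method transforms of the inverse
    observed information.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    y = z[z > threshold] - threshold
    n_exc = y.size
    if n_exc == 0:
        raise ValueError("no exceedances above the threshold")
    if n_exc < min_exceedances:
        warnings.warn(
            f"only {n_exc} exceedances above threshold {threshold:g}; "
            f"GPD estimates may be unstable", stacklevel=2)

    x0 = np.array(_moment_start(y))
    res = optimize.minimize(
        lambda t: _gpd_nll(t[0], t[1], y), x0,
        method="L-BFGS-B",
        bounds=[(None, None), shape_bounds],
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"GPD maximum-likelihood fit failed to converge: {res.message}")
    log_scale, shape = res.x
    scale = float(np.exp(log_scale))

    H = _numeric_hessian(lambda t: _gpd_nll(t[0], t[1], y), res.x)
    try:
        cov_t = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_t = np.full((2, 2), np.nan)
    # delta method from (log sigma, xi) to (sigma, xi)
    J = np.array([[scale, 0.0], [0.0, 1.0]])
    cov = J @ cov_t @ J.T
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(cov))
    return GPDFit(
        threshold=float(threshold), scale=scale, shape=float(shape),
        n_exceedances=int(n_exc), n_total=int(z.size),
        scale_se=float(ses[0]), shape_se=float(ses[1]), cov=cov,
        loglik=float(-res.fun),
    )


def return_level(fit: GPDFit, m: float) -> float:
    """Level exceeded on average once every ``m`` observations.

        x_m = k + sigma/xi * ((m*zeta)^xi - 1),

    with the log limit as xi -> 0; ``zeta`` is the exceedance rate.  Requires
    ``m * zeta >= 1`` (otherwise the level lies below the threshold and is not
    described by the tail model).
    """
    mz = m * fit.exceedance_rate
    if mz < 1:
        raise ValueError("m * exceedance_rate must be >= 1 for a POT return level")
    if abs(fit.shape) < XI_EPS:
        return fit.threshold + fit.scale * np.log(mz)
    return fit.threshold + fit.scale / fit.shape * (mz**fit.shape - 1.0)


# ------------------------------------------------------------ threshold tools

def default_threshold_grid(z: np.ndarray, lo: float = 0.50, hi: float = 0.995,
                           step: float = 0.005) -> np.ndarray:
    """Candidate thresholds at empirical quantiles lo..hi of ``z``."""
    qs = np.arange(lo, hi + step / 2, step)
    return np.unique(np.quantile(np.asarray(z, dtype=float), qs))


def mean_residual_life(z: np.ndarray, thresholds: np.ndarray,
                       conf: float = 0.95) -> pd.DataFrame:
    """Mean excess above each candidate threshold with a normal CI band.

    Columns: threshold, n_exceedances, mean_excess, se, lower, upper.
    Thresholds at or above the sample maximum are kept but flagged with
    ``n_exceedances = 0`` and NaN estimates rather than silently dropped.
    """
    z = np.asarray(z, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    rows = []
    for k in thresholds:
        exc = z[z > k] - k
        if exc.size == 0:
            rows.append((k, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        me = exc.mean()
        se = exc.std(ddof=1) / np.sqrt(exc.size) if exc.size > 1 else np.nan
        rows.append((k, exc.size, me, se, me - zcrit * se, me + zcrit * se))
    return pd.DataFrame(rows, columns=[
        "threshold", "n_exceedances", "mean_excess", "se", "lower", "upper"])


def parameter_stability(z: np.ndarray, thresholds: np.ndarray,
                        conf: float = 0.95, min_exceedances: int = 30) -> pd.DataFrame:
    """Refit the GPD at each candidate threshold; report shape and modified scale.

    The modified scale sigma* = sigma - xi*k is threshold-invariant in
    expectation wherever the GPD truly holds, so flat curves (within their
    confidence bands) indicate a valid threshold.  Per-threshold fit failures
    are recorded as NaN rows with ``ok = False``.
    """
    z = np.asarray(z, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    rows = []
    for k in thresholds:
        n_exc = int((z > k).sum())
        if n_exc < max(min_exceedances, 2):
            rows.append((k, n_exc, *[np.nan] * 8, False))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_gpd_pot(z, k, min_exceedances=1)
        except (ValueError, RuntimeError):
            rows.append((k, n_exc, *[np.nan] * 8, False))
            continue
        # delta method for sigma* = sigma - xi*k
        g = np.array([1.0, -k])
        var_ms = float(g @ fit.cov @ g)
        ms_se = np.sqrt(var_ms) if var_ms >= 0 else np.nan
        rows.append((
            k, n_exc,
            fit.shape, fit.shape_se,
            fit.shape - zcrit * fit.shape_se, fit.shape + zcrit * fit.shape_se,
            fit.modified_scale, ms_se,
            fit.modified_scale - zcrit * ms_se, fit.modified_scale + zcrit * ms_se,
            True,
        ))
    return pd.DataFrame(rows, columns=[
        "threshold", "n_exceedances",
        "shape", "shape_se", "shape_lower", "shape_upper",
        "modified_scale", "modified_scale_se",
        "modified_scale_lower", "modified_scale_upper", "ok"])


# ------------------------------------------------------------------ block maxima

@dataclass(frozen=True)
class GEVDParams:
    """GEVD location/scale/shape with ML standard errors."""

    location: float
    scale: float
    shape: float
    location_se: float = np.nan
    scale_se: float = np.nan
    shape_se: float = np.nan
    n_blocks: int = 0
    loglik: float = np.nan

    def cdf(self, x):
        # scipy's genextreme uses c = -shape
        return stats.genextreme.cdf(x, c=-self.shape, loc=self.location, scale=self.scale)


def _gevd_nll(theta: np.ndarray, m: np.ndarray) -> float:
    mu, log_sigma, xi = theta
    sigma = np.exp(log_sigma)
    s = (m - mu) / sigma
    n = m.size
    if abs(xi) < XI_EPS:
        return n * log_sigma + np.sum(s + np.exp(-s))
    arg = 1.0 + xi * s
    if np.any(arg <= 0):
        return np.inf
    return n * log_sigma + (1.0 + 1.0 / xi) * np.log(arg).sum() + np.sum(arg ** (-1.0 / xi))


def fit_gevd_block_maxima(values: np.ndarray, block_assignment: np.ndarray,
                          min_blocks: int = 20) -> GEVDParams:
    """Fit the GEVD to per-block maxima by maximum likelihood.

    ``block_assignment`` labels each value with its block; the maximum of each
    block is the fitting sample.  At least two blocks are required; fewer than
    ``min_blocks`` triggers a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(block_assignment)
    if values.shape != labels.shape:
        raise ValueError("values and block_assignment must have equal length")
    df = pd.DataFrame({"v": values, "b": labels})
    maxima = df.groupby("b", sort=False)["v"].max().to_numpy()
    if maxima.size < 2:
        raise ValueError("block-maxima fitting needs at least two blocks")
    if maxima.size < min_blocks:
        warnings.warn(f"only {maxima.size} blocks; GEVD estimates may be unstable",
                      stacklevel=2)

    # moment-based start (Gumbel approximation), then ML
    s0 = maxima.std(ddof=1) * np.sqrt(6) / np.pi
    mu0 = maxima.mean() - 0.5772 * s0
    x0 = np.array([mu0, np.log(max(s0, 1e-8)), 0.1])
    res = optimize.minimize(_gevd_nll, x0, args=(maxima,), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    mu, log_sigma, xi = res.x
    sigma = float(np.exp(log_sigma))

    H = _numeric_hessian(lambda t: _gevd_nll(t, maxima), res.x)
    try:
        cov_t = np.linalg.inv(H)
        J = np.diag([1.0, sigma, 1.0])
        cov = J @ cov_t @ J.T
        with np.errstate(invalid="ignore"):
            ses = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    return GEVDParams(
        location=float(mu), scale=sigma, shape=float(xi),
        location_se=float(ses[0]), scale_se=float(ses[1]), shape_se=float(ses[2]),
        n_blocks=int(maxima.size), loglik=float(-res.fun),
    )
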