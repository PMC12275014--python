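"""Multivariate tail dependence: TPDM estimation and extreme PCA.

Pipeline: each column of a deviation-score matrix is rank-transformed to an
empirical CDF ``F = rank/(n+1)`` and mapped to pseudo-Frechet values
``x = (-log F)^(-1/2)``, giving common heavy-tailed margins with tail index
alpha = 2 (CDF exp(-x^-2)).  Rows are written in polar coordinates
``x = r * omega`` with the L2 norm; rows whose radius exceeds the empirical
q-quantile (default q = 0.95) are the multivariate extremes.  The tail
pairwise dependence matrix (TPDM) is the second-moment matrix of the angular
components of those extreme rows,

    sigma_ij = c / n_exc * sum_{r_n > r0} omega_ni * omega_nj,

the extremal analogue of a covariance matrix: sigma_ij = 0 for variables
that are independent in the joint tail, and the diagonal carries the
marginal tail scale.  Its eigendecomposition yields "extreme principal
components": directions ordered by the tail scale they explain.

Two normalizations of the constant ``c`` are supported.  ``"printed"`` uses
c = 2, which fixes trace = 2 for any dimension; ``"unit"`` (the default)
uses c = D so the diagonal is 1 under unit-scale Frechet(2) margins and the
TPDM of a max-linear generator converges to B @ B.T.  The two differ by the
positive scalar D/2 only, so eigenvectors, scale proportions, and
contribution rankings are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PseudoFrechetMatrix",
    "PolarDecomposition",
    "TPDM",
    "ExtremeEigenBasis",
    "to_pseudo_frechet",
    "polar_decompose_threshold",
    "estimate_tpdm",
    "extreme_pca",
    "loadings_contributions",
    "project_scores",
    "tpdm_from_zscores",
]

TAIL_INDEX = 2.0


@dataclass(frozen=True)
class PseudoFrechetMatrix:
    """Marginally rank/Frechet-transformed data with tail index 2."""

    values: np.ndarray
    columns: tuple[str, ...]
    n_dropped_rows: int = 0

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PolarDecomposition:
    """L2 polar coordinates of pseudo-Frechet rows plus a radial threshold."""

    radius: np.ndarray
    angles: np.ndarray
    radial_threshold: float
    quantile: float
    exceedance_mask: np.ndarray = field(repr=False)
    columns: tuple[str, ...] = ()

    @property
    def n_exceedances(self) -> int:
        return int(self.exceedance_mask.sum())


@dataclass(frozen=True)
class TPDM:
    """Tail pairwise dependence matrix with its estimation provenance."""

    matrix: np.ndarray
    normalization: str
    radial_threshold: float
    n_exceedances: int
    columns: tuple[str, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        cols = self.columns or tuple(f"var_{j:04d}" for j in range(self.matrix.shape[0]))
        return pd.DataFrame(self.matrix, index=list(cols), columns=list(cols))


@dataclass(frozen=True)
class ExtremeEigenBasis:
    """Eigendecomposition of a TPDM, ordered by descending tail scale."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scale_proportions: np.ndarray
    columns: tuple[str, ...] = ()


def to_pseudo_frechet(z, min_distinct: int = 20) -> PseudoFrechetMatrix:
    """Rank-transform each column and map it to Frechet(2) pseudo-observations.

    ``F = rank/(n+1)`` (mid-ranks for ties) keeps F strictly inside (0, 1);
    ``x = (-log F)^(-1/2)`` then has CDF exp(-x^-2) up to rank discretization.
    Rows containing any missing value are dropped (complete-case) with a
    count recorded; constant columns are rejected by name.
    """
    if isinstance(z, pd.DataFrame):
        df = z.drop(columns=["subject_id"], errors="ignore")
        columns = tuple(str(c) for c in df.columns)
        values = df.to_numpy(dtype=float)
    else:
        values = np.asarray(z, dtype=float)
        columns = tuple(f"var_{j:04d}" for j in range(values.shape[1]))
    keep = np.all(np.isfinite(values), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} rows with missing values", stacklevel=2)
    values = values[keep]
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two complete rows")

    out = np.empty_like(values)
    for j, name in enumerate(columns):
        col = values[:, j]
        n_distinct = np.unique(col).size
        if n_distinct == 1:
            raise ValueError(f"column {name!r} is constant; cannot rank-transform")
        if n_distinct < min_distinct:
            warnings.warn(f"column {name!r} has only {n_distinct} distinct values",
                          stacklevel=2)
        F = stats.rankdata(col, method="average") / (n + 1)
        out[:, j] = (-np.log(F)) ** (-1.0 / TAIL_INDEX)
    return PseudoFrechetMatrix(values=out, columns=columns, n_dropped_rows=n_dropped)


def polar_decompose_threshold(x: PseudoFrechetMatrix, quantile: float = 0.95,
                              min_exceedances: int = 20) -> PolarDecomposition:
    """L2 polar coordinates r, omega and the empirical q-quantile radial cut."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly in (0, 1)")
    v = x.values
    r = np.linalg.norm(v, axis=1)
    omega = v / r[:, None]
    r0 = float(np.quantile(r, quantile))
    mask = r > r0
    n_exc = int(mask.sum())
    if n_exc < min_exceedances:
        warnings.warn(f"only {n_exc} radial exceedances above the "
                      f"{quantile:g}-quantile", stacklevel=2)
    return PolarDecomposition(radius=r, angles=omega, radial_threshold=r0,
                              quantile=quantile, exceedance_mask=mask,
                              columns=x.columns)


def estimate_tpdm(polar: PolarDecomposition, normalization: str = "unit") -> TPDM:
    """Second-moment matrix of the extreme angular components.

    ``normalization="printed"`` multiplies the angular second moment by 2
    (trace is exactly 2 in any dimension); ``"unit"`` multiplies by D so the
    diagonal estimates the squared marginal tail scale (1 after the rank
    transform) and the trace is exactly D.
    """
    if normalization not in ("printed", "unit"):
        raise ValueError("normalization must be 'printed' or 'unit'")
    W = polar.angles[polar.exceedance_mask]
    n_exc = W.shape[0]
    if n_exc == 0:
        raise ValueError("no radial exceedances; cannot estimate the TPDM")
    d = W.shape[1]
    const = 2.0 if normalization == "printed" else float(d)
    sigma = const / n_exc * (W.T @ W)
    sigma = (sigma + sigma.T) / 2  # enforce exact symmetry
    return TPDM(matrix=sigma, normalization=normalization,
                radial_threshold=polar.radial_threshold,
                n_exceedances=n_exc, columns=polar.columns)


def extreme_pca(tpdm: TPDM, psd_tol: float = 1e-10) -> ExtremeEigenBasis:
    """Eigendecomposition of the TPDM, sorted by descending tail scale.

    Eigenvector signs are fixed by making each vector's largest-magnitude
    entry positive.  Symmetry is required; eigenvalues below ``-psd_tol``
    raise (the TPDM is positive semidefinite in theory).
    """
    S = np.asarray(tpdm.matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("TPDM must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("TPDM must be symmetric")
    lam, U = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    if lam[-1] < -psd_tol * max(1.0, lam[0]):
        raise ValueError(f"TPDM has a significantly negative eigenvalue: {lam[-1]:g}")
    lam = np.clip(lam, 0.0, None)
    # sign convention: dominant entry of each eigenvector positive
    for l in range(U.shape[1]):
        piv = np.argmax(np.abs(U[:, l]))
        if U[piv, l] < 0:
            U[:, l] = -U[:, l]
    props = lam / lam.sum() if lam.sum() > 0 else np.full_like(lam, np.nan)
    return ExtremeEigenBasis(eigenvalues=lam, eigenvectors=U,
                             scale_proportions=props, columns=tpdm.columns)


def loadings_contributions(basis: ExtremeEigenBasis, n_components: int,
                           mode: str = "printed") -> tuple[np.ndarray, np.ndarray]:
    """Per-variable loadings f and contributions c of the top components.

    ``mode="printed"`` uses f_l = u_l * lambda_l and c_dl = f_dl^2 / lambda_l
    (so contributions for component l sum to lambda_l); ``mode="conventional"``
    uses f_l = u_l * sqrt(lambda_l), making each component's contributions sum
    to 1.  Rankings of variables within a component agree between modes.
    A zero eigenvalue yields zero contributions with a warning.
    """
    if mode not in ("printed", "conventional"):
        raise ValueError("mode must be 'printed' or 'conventional'")
    d = basis.eigenvectors.shape[0]
    if not 1 <= n_components <= d:
        raise ValueError(f"n_components must be in [1, {d}]")
    lam = basis.eigenvalues[:n_components]
    U = basis.eigenvectors[:, :n_components]
    if np.any(lam == 0):
        warnings.warn("zero eigenvalue: contributions defined as 0", stacklevel=2)
    if mode == "printed":
        f = U * lam[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(lam[None, :] > 0, f**2 / lam[None, :], 0.0)
    else:
        f = U * np.sqrt(lam[None, :])
        c = np.where(lam[None, :] > 0, U**2, 0.0)
    return f, c


def project_scores(x: PseudoFrechetMatrix, basis: ExtremeEigenBasis,
                   n_components: int, score_map: str = "log") -> np.ndarray:
    """Per-subject component scores: project (pre-mapped) pseudo-Frechet rows.

    ``score_map="log"`` (default) takes the elementwise natural log first,
    mapping the positive half-line onto the real line so projections are
    unconstrained; ``"raw"`` projects the pseudo-Frechet values directly.
    """
    if score_map not in ("log", "raw"):
        raise ValueError("score_map must be 'log' or 'raw'")
    d = basis.eigenvectors.shape[0]
    if x.n_variables != d:
        raise ValueError("column count of x must match the eigenbasis dimension")
    if not 1 <= n_components <= d:
        raise ValueError(f"n_components must be in [1, {d}]")
    v = np.log(x.values) if score_map == "log" else x.values
    return v @ basis.eigenvectors[:, :n_components]


def tpdm_from_zscores(z, quantile: float = 0.95,
                      normalization: str = "unit") -> tuple[TPDM, PolarDecomposition, PseudoFrechetMatrix]:
    """Convenience chain: z-scores -> pseudo-Frechet -> polar -> TPDM."""
    x = to_pseudo_frechet(z)
    polar = polar_decompose_threshold(x, quantile=quantile)
    return estimate_tpdm(polar, normalization=normalization), polar, x
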