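"""Component-phenotype association screening.

Each component score is correlated with every behavioral phenotype:
point-biserial (i.e., Pearson against a 0/1 coding) when the phenotype has
exactly two distinct non-missing values, Spearman rank correlation
otherwise.  p-values use the t approximation

    t = r * sqrt((n - 2) / (1 - r^2)),   p = 2 * P(T_{n-2} > |t|),

(with an optional permutation alternative for small n) and the family-wise
error rate is controlled by Bonferroni across the full grid of
(#phenotypes x #components) tests.  Comparators: eigendecomposition of the
ordinary correlation matrix ("standard PCA") and a per-subject count of
deviation scores beyond a cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "associate_components",
    "aggregate_by_phenotype",
    "standard_pca_baseline",
    "deviation_count_score",
]

_P_FLOOR = 1e-300


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, _P_FLOOR, np.clip(p, _P_FLOOR, 1.0))


def _permutation_pvalue(x: np.ndarray, y: np.ndarray, r_obs: float,
                        rank_x: bool, n_perm: int, rng: np.random.Generator) -> float:
    xr = stats.rankdata(x) if rank_x else x
    yr = stats.rankdata(y) if rank_x else y
    xc = (xr - xr.mean()) / xr.std()
    yc = (yr - yr.mean()) / yr.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(xc)
        if abs(np.mean(perm * yc)) >= abs(r_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _batch_spearman(P: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman between columns of P and columns of S (no missing)."""
    n = P.shape[0]
    Pr = stats.rankdata(P, axis=0)
    Sr = stats.rankdata(S, axis=0)
    Pr = (Pr - Pr.mean(axis=0)) / Pr.std(axis=0)
    Sr = (Sr - Sr.mean(axis=0)) / Sr.std(axis=0)
    r = Pr.T @ Sr / n
    return r, _t_pvalue(r, n)


def associate_components(
    scores,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    n_components: int | None = None,
    categories: dict[str, str] | None = None,
    p_method: str = "approx",
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate every phenotype with every component and flag Bonferroni hits.

    ``scores`` is subject-by-component (array or DataFrame); ``phenotypes``
    a subject-aligned table (a ``subject_id`` column is ignored for testing).
    Returns one row per (phenotype, component) with columns phenotype,
    category, component, test, correlation, p_value, neg_log10_p,
    bonferroni_significant, n_used; sorted by neg_log10_p descending.
    Phenotypes that are constant or have fewer than 3 non-missing values are
    skipped with a warning.  The Bonferroni threshold is
    ``alpha / (#tested phenotypes * #components)``.
    """
    if isinstance(scores, pd.DataFrame):
        S = scores.drop(columns=["subject_id"], errors="ignore").to_numpy(dtype=float)
    else:
        S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    L = n_components or S.shape[1]
    if not 1 <= L <= S.shape[1]:
        raise ValueError(f"n_components must be in [1, {S.shape[1]}]")
    S = S[:, :L]
    pheno = phenotypes.drop(columns=["subject_id"], errors="ignore")
    if len(pheno) != S.shape[0]:
        raise ValueError("scores and phenotypes must have the same number of rows")
    rng = np.random.default_rng(seed)

    rows = []
    complete_cont: list[str] = []
    for name in pheno.columns:
        v = pheno[name].to_numpy(dtype=float)
        finite = np.isfinite(v)
        vals = np.unique(v[finite])
        if finite.sum() < 3:
            warnings.warn(f"phenotype {name!r} has <3 non-missing values; skipped",
                          stacklevel=2)
            continue
        if vals.size < 2:
            warnings.warn(f"phenotype {name!r} is constant; skipped", stacklevel=2)
            continue
        binary = vals.size == 2
        if not binary and finite.all() and p_method == "approx":
            complete_cont.append(name)   # vectorized Spearman path
            continue
        for l in range(L):
            m = finite & np.isfinite(S[:, l])
            x, s = v[m], S[m, l]
            n = int(m.sum())
            if binary:
                code = (x == vals[1]).astype(float)
                r = float(np.corrcoef(code, s)[0, 1])
                test = "point_biserial"
                rank_x = False
            else:
                r = float(stats.spearmanr(x, s).statistic)
                test = "spearman"
                rank_x = True
            if p_method == "permutation" or (p_method == "auto" and n < 50):
                p = _permutation_pvalue(x, s, r, rank_x, n_perm, rng)
            else:
                p = float(_t_pvalue(np.array(r), n))
            rows.append((name, test, l, r, p, n))

    if complete_cont:
        P = pheno[complete_cont].to_numpy(dtype=float)
        r_mat, p_mat = _batch_spearman(P, S)
        n = P.shape[0]
        for i, name in enumerate(complete_cont):
            for l in range(L):
                rows.append((name, "spearman", l, float(r_mat[i, l]),
                             float(p_mat[i, l]), n))

    df = pd.DataFrame(rows, columns=["phenotype", "test", "component",
                                     "correlation", "p_value", "n_used"])
    n_pheno_tested = df["phenotype"].nunique()
    m = n_pheno_tested * L
    df["neg_log10_p"] = -np.log10(df["p_value"])
    df["bonferroni_significant"] = df["p_value"] <= alpha / max(m, 1)
    df["n_tests"] = m
    if categories:
        df.insert(1, "category", df["phenotype"].map(categories).fillna("uncategorized"))
    return df.sort_values("neg_log10_p", ascending=False, ignore_index=True)


def aggregate_by_phenotype(table: pd.DataFrame) -> pd.DataFrame:
    """Most significant component per phenotype (max neg_log10_p)."""
    idx = table.groupby("phenotype")["neg_log10_p"].idxmax()
    return table.loc[idx].sort_values("neg_log10_p", ascending=False,
                                      ignore_index=True)


def standard_pca_baseline(z, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation-matrix PCA of the deviation scores, as a bulk comparator.

    Returns ``(scores, eigenvectors, variance_proportions)`` with the same
    layout conventions as extreme PCA (descending eigenvalues, each
    eigenvector's dominant entry positive).  Scores project the standardized
    z columns.  Correlation eigenvalues always sum to the number of columns.
    """
    if isinstance(z, pd.DataFrame):
        Z = z.drop(columns=["subject_id"], errors="ignore")
        names = list(Z.columns)
        Z = Z.to_numpy(dtype=float)
    else:
        Z = np.asarray(z, dtype=float)
        names = [f"var_{j:04d}" for j in range(Z.shape[1])]
    d = Z.shape[1]
    if d < 2:
        raise ValueError("need at least 2 variables")
    sd = Z.std(axis=0)
    const = [names[j] for j in np.nonzero(sd == 0)[0]]
    if const:
        raise ValueError(f"constant column(s): {', '.join(const)}")
    if not 1 <= n_components <= d:
        raise ValueError(f"n_components must be in [1, {d}]")
    Zs = (Z - Z.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    lam, U = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, U = np.clip(lam[order], 0, None), U[:, order]
    for l in range(d):
        piv = np.argmax(np.abs(U[:, l]))
        if U[piv, l] < 0:
            U[:, l] = -U[:, l]
    return Zs @ U[:, :n_components], U, lam / lam.sum()


def deviation_count_score(z, cutoff: float = 1.96) -> pd.DataFrame:
    """Per-subject counts of deviations beyond ``+-cutoff`` (default 1.96)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(z, pd.DataFrame):
        Z = z.drop(columns=["subject_id"], errors="ignore").to_numpy(dtype=float)
    else:
        Z = np.asarray(z, dtype=float)
    pos = (Z > cutoff).sum(axis=1)
    neg = (Z < -cutoff).sum(axis=1)
    return pd.DataFrame({"n_positive": pos, "n_negative": neg,
                         "n_total": pos + neg})
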