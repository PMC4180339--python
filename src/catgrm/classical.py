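"""Descriptives, reliability and IRT-assumption screens.

Covers step 1 (item descriptives, Cronbach alpha, item-rest correlation)
and step 2 (PCA unidimensionality rules, one-factor ML CFA with fit
indices, residual local-independence flags, and Loevinger scalability).

Conventions, stated because they change digits:

* Cronbach alpha uses population variances (divide by n).
* PCA and CFA operate on the Pearson correlation matrix of the raw
  ordinal scores (no polychorics).
* SRMR averages squared residuals over the lower triangle including the
  diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ResponseMatrix

__all__ = [
    "DescriptivesTable",
    "cronbach_alpha",
    "descriptives",
    "pca_screen",
    "cfa_one_factor",
    "cfa_from_correlation",
    "local_independence_flags",
    "mokken_scalability",
]


# ---------------------------------------------------------------------------
# step 1: descriptives and reliability


@dataclass
class DescriptivesTable:
    items: pd.DataFrame  # per-item counts, mean, sd, alpha_if_deleted, item_rest_r
    cronbach_alpha: float
    total_mean: float
    total_sd: float
    n_persons: int


def cronbach_alpha(X: np.ndarray) -> float:
    """alpha = K/(K-1) * (1 - sum(item var) / total var), population variances."""
    X = np.asarray(X, dtype=float)
    K = X.shape[1]
    if K < 2:
        raise ValueError("need at least 2 items")
    total_var = X.sum(axis=1).var(ddof=0)
    if total_var == 0:
        raise ValueError("total score has zero variance: alpha undefined")
    return (K / (K - 1)) * (1.0 - X.var(axis=0, ddof=0).sum() / total_var)


def descriptives(matrix: ResponseMatrix) -> DescriptivesTable:
    X = matrix.responses.astype(float)
    n, K = X.shape
    if n < 2 or K < 2:
        raise ValueError("need at least 2 persons and 2 items")
    m = int(matrix.responses.max(initial=0))
    total = X.sum(axis=1)
    alpha = cronbach_alpha(X)

    rows = []
    for j in range(K):
        col = matrix.responses[:, j]
        counts = np.bincount(col, minlength=m + 1)
        rest = total - X[:, j]
        if X[:, j].std(ddof=0) == 0 or rest.std(ddof=0) == 0:
            r_rest = np.nan
        else:
            r_rest = float(np.corrcoef(X[:, j], rest)[0, 1])
        others = np.delete(X, j, axis=1)
        try:
            a_del = cronbach_alpha(others)
        except ValueError:
            a_del = np.nan
        rows.append(
            {"item": j + 1,
             **{f"n{k}": int(counts[k]) for k in range(m + 1)},
             "mean": float(X[:, j].mean()),
             "sd": float(X[:, j].std(ddof=0)),
             "alpha_if_deleted": a_del,
             "item_rest_r": r_rest}
        )
    return DescriptivesTable(
        items=pd.DataFrame(rows).set_index("item"),
        cronbach_alpha=alpha,
        total_mean=float(total.mean()),
        total_sd=float(total.std(ddof=0)),
        n_persons=n,
    )


# ---------------------------------------------------------------------------
# step 2: unidimensionality (PCA rules + one-factor CFA)


def _correlation(matrix: ResponseMatrix) -> np.ndarray:
    X = matrix.responses.astype(float)
    sds = X.std(axis=0, ddof=0)
    dead = np.where(sds == 0)[0]
    if dead.size:
        raise ValueError(f"constant item(s) {[int(d) + 1 for d in dead]}: correlation undefined")
    return np.corrcoef(X, rowvar=False)


@dataclass
class PCAScreen:
    eigenvalues: np.ndarray
    prop_var_first: float
    ratio_first_second: float
    pass_20pct: bool
    pass_ratio4: bool


def pca_screen(
    matrix: ResponseMatrix, prop_var_min: float = 0.20, ratio_min: float = 4.0
) -> PCAScreen:
    """Eigenvalues of the item correlation matrix with the two printed rules:
    first component explains >= 20% of variance, and at least `ratio_min`
    times the second component's share."""
    R = _correlation(matrix)
    eig = np.linalg.eigvalsh(R)[::-1]
    eig = np.maximum(eig, 0.0)
    prop = float(eig[0] / R.shape[0])
    ratio = float(eig[0] / eig[1]) if eig[1] > 0 else np.inf
    return PCAScreen(
        eigenvalues=eig,
        prop_var_first=prop,
        ratio_first_second=ratio,
        pass_20pct=prop >= prop_var_min,
        pass_ratio4=ratio >= ratio_min,
    )


@dataclass
class CFAFit:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    residuals: np.ndarray
    heywood: bool
    n_persons: int
    baseline_chi2: float = np.nan
    baseline_df: int = 0


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    p = S.shape[0]
    return logdet_sigma + float(np.trace(np.linalg.solve(sigma, S))) - logdet_s - p


def cfa_one_factor(matrix: ResponseMatrix) -> CFAFit:
    """Maximum-likelihood one-factor fit to the Pearson correlation matrix.

    Model-implied matrix is ``lambda lambda' + diag(psi)``; the chi-square
    is ``(n-1)`` times the ML discrepancy, CFI/TLI are computed against the
    independence baseline, RMSEA's 90% CI inverts the noncentral
    chi-square, and SRMR averages squared residual correlations over the
    lower triangle including the diagonal.  A Heywood case (uniqueness at
    the zero bound) is flagged but the fit is still returned.
    """
    if matrix.n_persons <= matrix.n_items:
        raise ValueError("need more persons than items for CFA")
    return cfa_from_correlation(_correlation(matrix), matrix.n_persons)


def cfa_from_correlation(S: np.ndarray, n: int) -> CFAFit:
    """One-factor ML fit given a correlation matrix and sample size."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]

    eigval, eigvec = np.linalg.eigh(S)
    lam0 = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.1))
    if lam0.sum() < 0:
        lam0 = -lam0
    lam0 = np.clip(lam0, -0.98, 0.98)
    psi0 = np.clip(1.0 - lam0**2, 0.02, None)

    def unpack(x):
        return x[:p], np.exp(x[p:])

    def objective(x):
        lam, psi = unpack(x)
        return _ml_discrepancy(S, np.outer(lam, lam) + np.diag(psi))

    res = optimize.minimize(
        objective,
        np.concatenate([lam0, np.log(psi0)]),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam, psi = unpack(res.x)
    if lam.sum() < 0:
        lam = -lam
    sigma = np.outer(lam, lam) + np.diag(psi)
    heywood = bool(np.any(psi < 5e-3) or np.any(np.abs(lam) > 1.0))

    F = max(float(res.fun), 0.0)
    df = p * (p + 1) // 2 - 2 * p
    chi2 = (n - 1) * F
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan

    # independence baseline: sigma = I for a correlation input
    F_base = max(_ml_discrepancy(S, np.eye(p)), 0.0)
    df_base = p * (p - 1) // 2
    chi2_base = (n - 1) * F_base

    d = max(chi2 - df, 0.0)
    d_base = max(chi2_base - df_base, 0.0)
    cfi = 1.0 if d_base == 0 else 1.0 - d / max(d_base, d)
    if chi2_base > 0 and df_base > 0 and df > 0:
        denom = chi2_base / df_base - 1.0
        tli = (chi2_base / df_base - chi2 / df) / denom if denom > 0 else 1.0
        tli = min(tli, 1.0)
    else:
        tli = np.nan
    rmsea = np.sqrt(d / (df * (n - 1))) if df > 0 else np.nan
    rmsea_ci = _rmsea_ci(chi2, df, n) if df > 0 else (np.nan, np.nan)

    resid = S - sigma
    tril = np.tril_indices(p)
    srmr = float(np.sqrt((resid[tril] ** 2).mean()))

    return CFAFit(
        loadings=lam, uniquenesses=psi, chi2=float(chi2), df=df, p_value=p_value,
        cfi=float(min(cfi, 1.0)), tli=float(tli), rmsea=float(rmsea),
        rmsea_ci90=rmsea_ci, srmr=srmr, residuals=resid, heywood=heywood,
        n_persons=n, baseline_chi2=float(chi2_base), baseline_df=df_base,
    )


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% CI by inverting the noncentral chi-square at the observed statistic."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2  # 0.95, 0.05

    def ncp_for(q: float) -> float:
        # find noncentrality nc with P(X2_{df,nc} <= chi2) = q
        if stats.ncx2.cdf(chi2, df, 0.0) < q:
            return 0.0
        hi = max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > q:
            hi *= 2
            if hi > 1e8:
                return hi
        return float(optimize.brentq(lambda nc: stats.ncx2.cdf(chi2, df, nc) - q, 0.0, hi))

    nc_lo, nc_hi = ncp_for(lo_q), ncp_for(hi_q)
    return (
        float(np.sqrt(nc_lo / (df * (n - 1)))),
        float(np.sqrt(nc_hi / (df * (n - 1)))),
    )


def local_independence_flags(residuals: np.ndarray, threshold: float = 0.2) -> list[tuple[int, int, float]]:
    """Off-diagonal residual correlations with |r| > threshold, as 1-based pairs."""
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("residual matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("residual matrix must be symmetric")
    flags = []
    p = R.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            if abs(R[i, j]) > threshold:
                flags.append((i + 1, j + 1, float(R[i, j])))
    return flags


# ---------------------------------------------------------------------------
# step 2: monotonicity / Mokken scalability


@dataclass
class ScalabilityReport:
    pairwise_h: pd.DataFrame
    item_h: pd.Series
    overall_h: float
    flagged_items: list[int]
    excluded_items: list[int] = field(default_factory=list)


def _max_covariance(x: np.ndarray, y: np.ndarray) -> float:
    """Largest covariance attainable given both marginals: sort both ways."""
    return float(np.cov(np.sort(x), np.sort(y), ddof=0)[0, 1])


def mokken_scalability(matrix: ResponseMatrix, threshold: float = 0.3) -> ScalabilityReport:
    """Loevinger scalability: H_ij = cov / cov_max with cov_max from the
    comonotone arrangement of the observed marginals; item H_j pools
    covariances over partners; items with H_j < threshold are flagged.
    Zero-variance items are excluded with a warning."""
    X = matrix.responses.astype(float)
    K = X.shape[1]
    if K < 2:
        raise ValueError("need at least 2 items")
    sds = X.std(axis=0, ddof=0)
    excluded = [j + 1 for j in range(K) if sds[j] == 0]
    if excluded:
        warnings.warn(f"zero-variance item(s) excluded from scalability: {excluded}", stacklevel=2)
    keep = [j for j in range(K) if sds[j] > 0]

    ids = [j + 1 for j in keep]
    cov = np.zeros((len(keep), len(keep)))
    cov_max = np.zeros_like(cov)
    for a, ja in enumerate(keep):
        for b, jb in enumerate(keep):
            if a >= b:
                continue
            c = float(np.cov(X[:, ja], X[:, jb], ddof=0)[0, 1])
            cm = _max_covariance(X[:, ja], X[:, jb])
            cov[a, b] = cov[b, a] = c
            cov_max[a, b] = cov_max[b, a] = cm

    with np.errstate(divide="ignore", invalid="ignore"):
        H_pair = np.where(cov_max > 0, cov / cov_max, np.nan)
    np.fill_diagonal(H_pair, np.nan)

    item_h = pd.Series(
        [cov[a].sum() / cov_max[a].sum() if cov_max[a].sum() > 0 else np.nan
         for a in range(len(keep))],
        index=pd.Index(ids, name="item"),
        name="H_j",
    )
    triu = np.triu_indices(len(keep), 1)
    denom = cov_max[triu].sum()
    overall = float(cov[triu].sum() / denom) if denom > 0 else np.nan
    flagged = [int(i) for i, h in item_h.items() if np.isnan(h) or h < threshold]
    return ScalabilityReport(
        pairwise_h=pd.DataFrame(H_pair, index=ids, columns=ids),
        item_h=item_h,
        overall_h=overall,
        flagged_items=flagged,
        excluded_items=excluded,
    )
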