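"""Graded response model: probabilities, information, calibration and scoring.

Pure logistic metric throughout — no 1.7 scaling constant.  Boundary
curves are ``P*_k(theta) = expit(alpha * (theta - beta_k))`` for
``k = 1..m`` with ``P*_0 = 1`` and ``P*_{m+1} = 0``; category
probabilities are differences of adjacent boundary curves.

Calibration is marginal maximum likelihood via EM with Gauss-Hermite
quadrature under a standard-normal latent density.  Trait scoring offers
EAP (posterior mean on an equally spaced grid under an N(0,1) prior) and
bounded MLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .core import Item, ItemBank, ResponseMatrix

__all__ = [
    "PROB_FLOOR",
    "THETA_GRID",
    "category_probabilities",
    "item_information",
    "test_information",
    "information_curve",
    "crc_table",
    "GRMFit",
    "fit_grm_mml",
    "ThetaEstimate",
    "estimate_theta",
    "eap_scores",
    "mean_theta_by_response",
]

#: floor applied to category probabilities in likelihood / information code
PROB_FLOOR = 1e-10

#: default EAP grid: 61 equally spaced nodes on [-4.5, 4.5]
THETA_GRID = np.linspace(-4.5, 4.5, 61)


def _boundary(alpha: float | np.ndarray, betas: np.ndarray, theta) -> np.ndarray:
    """P*_k for k=1..m; shape (..., m)."""
    theta = np.asarray(theta, dtype=float)
    return expit(alpha * (theta[..., None] - betas))


def category_probabilities(item: Item, theta) -> np.ndarray:
    """Category probability vector(s) P_0..P_m at ``theta`` (scalar or array).

    Returns shape ``theta.shape + (m+1,)``; rows sum to 1 exactly up to
    floating point because categories are differences of boundary curves.
    """
    betas = np.asarray(item.betas, dtype=float)
    pstar = _boundary(item.alpha, betas, theta)
    theta = np.asarray(theta, dtype=float)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    cum = np.concatenate([ones, pstar, zeros], axis=-1)
    return -np.diff(cum, axis=-1)


def item_information(item: Item, theta) -> np.ndarray | float:
    """GRM Fisher information I(theta) = sum_k (w_k - w_{k+1})^2 / P_k.

    ``w_k = alpha * P*_k * (1 - P*_k)`` with ``w_0 = w_{m+1} = 0``.
    Probabilities are floored at PROB_FLOOR to avoid division underflow.
    """
    theta_arr = np.asarray(theta, dtype=float)
    betas = np.asarray(item.betas, dtype=float)
    pstar = _boundary(item.alpha, betas, theta_arr)
    w = item.alpha * pstar * (1.0 - pstar)
    zeros = np.zeros(theta_arr.shape + (1,))
    w = np.concatenate([zeros, w, zeros], axis=-1)  # w_0..w_{m+1}
    probs = np.maximum(category_probabilities(item, theta_arr), PROB_FLOOR)
    info = ((w[..., :-1] - w[..., 1:]) ** 2 / probs).sum(axis=-1)
    return float(info) if np.isscalar(theta) or np.asarray(theta).ndim == 0 else info


def test_information(bank: ItemBank, theta, subset=None) -> np.ndarray | float:
    """Sum of item informations over ``subset`` (1-based ids; default all)."""
    ids = list(subset) if subset is not None else [it.id for it in bank]
    unknown = set(ids) - {it.id for it in bank}
    if unknown:
        raise KeyError(f"subset ids not in bank: {sorted(unknown)}")
    if not ids:
        import warnings

        warnings.warn("empty item subset: test information is 0", stacklevel=2)
        return np.zeros(np.shape(theta)) if np.ndim(theta) else 0.0
    total = sum(item_information(bank[i], theta) for i in ids)
    return total


def information_curve(bank: ItemBank, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Test-information curve on a theta grid (full bank), exportable to CSV."""
    grid = THETA_GRID if grid is None else np.asarray(grid, dtype=float)
    return pd.DataFrame({"theta": grid, "information": test_information(bank, grid)})


def crc_table(item: Item, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Category response curves for one item on a theta grid."""
    grid = THETA_GRID if grid is None else np.asarray(grid, dtype=float)
    probs = category_probabilities(item, grid)
    df = pd.DataFrame(probs, columns=[f"p{k}" for k in range(item.n_categories)])
    df.insert(0, "theta", grid)
    return df


# ---------------------------------------------------------------------------
# marginal maximum likelihood calibration (EM, Gauss-Hermite quadrature)


@dataclass
class GRMFit:
    """Result of an MML-EM calibration."""

    bank: ItemBank
    standard_errors: pd.DataFrame
    log_likelihood: float
    n_iterations: int
    converged: bool
    quadrature_spec: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for integration against N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    return nodes, weights / weights.sum()


def _log_category_matrix(alphas, betas, nodes) -> np.ndarray:
    """log P_k(theta_q) for every item; shape (K, Q, m+1)."""
    pstar = expit(alphas[:, None, None] * (nodes[None, :, None] - betas[:, None, :]))
    K, Q, m = pstar.shape
    cum = np.concatenate(
        [np.ones((K, Q, 1)), pstar, np.zeros((K, Q, 1))], axis=2
    )
    probs = np.maximum(-np.diff(cum, axis=2), PROB_FLOOR)
    return np.log(probs)


def _person_loglik(logp: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Per-person log-likelihood at each node; shape (n, Q)."""
    n, K = responses.shape
    Q = logp.shape[1]
    ll = np.zeros((n, Q))
    for j in range(K):
        ll += logp[j, :, responses[:, j]]
    return ll


def _item_objective(params: np.ndarray, nodes: np.ndarray, r: np.ndarray, m: int):
    """Negative expected complete-data log-likelihood for one item + gradient.

    ``r`` is the (Q, m+1) table of expected response counts at each node.
    Parameters are (alpha, beta_1..beta_m), alpha bounded positive by caller.
    """
    alpha, betas = params[0], params[1:]
    pstar = expit(alpha * (nodes[:, None] - betas[None, :]))  # (Q, m)
    Q = nodes.shape[0]
    cum = np.concatenate([np.ones((Q, 1)), pstar, np.zeros((Q, 1))], axis=1)
    probs = np.maximum(-np.diff(cum, axis=1), PROB_FLOOR)  # (Q, m+1)
    nll = -(r * np.log(probs)).sum()

    # dP*_k/dalpha and dP*_k/dbeta_k, padded so index k runs 0..m+1
    dp = pstar * (1.0 - pstar)
    pad = np.zeros((Q, 1))
    da = np.concatenate([pad, dp * (nodes[:, None] - betas[None, :]), pad], axis=1)
    ratio = r / probs  # (Q, m+1)
    # dP_k = dP*_k - dP*_{k+1}
    grad_a = -(ratio * (da[:, :-1] - da[:, 1:])).sum()
    grad_b = np.empty(m)
    for k in range(m):
        dbk = -alpha * dp[:, k]  # dP*_{k+1}/dbeta_{k+1} (0-indexed column k)
        # boundary k+1 enters P_k with coefficient -1 and P_{k+1} with +1
        grad_b[k] = (ratio[:, k] * dbk - ratio[:, k + 1] * dbk).sum()
    return nll, np.concatenate([[grad_a], grad_b])


def _start_values(responses: np.ndarray, m: int) -> np.ndarray:
    """Heuristic starts: alpha=1.5, betas from inverse-logistic cumulative props."""
    n = responses.shape[0]
    alpha0 = 1.5
    betas = []
    for k in range(1, m + 1):
        p = np.clip((responses >= k).mean(), 1.0 / (n + 1), n / (n + 1.0))
        betas.append(-np.log(p / (1 - p)) / alpha0)
    betas = np.asarray(betas)
    # enforce strict order
    for k in range(1, m):
        if betas[k] <= betas[k - 1]:
            betas[k] = betas[k - 1] + 0.1
    return np.concatenate([[alpha0], betas])


def fit_grm_mml(
    matrix: ResponseMatrix,
    n_nodes: int = 41,
    tol: float = 1e-6,
    max_iter: int = 500,
    labels: list[str] | None = None,
) -> GRMFit:
    """Calibrate a GRM by marginal maximum likelihood (EM).

    E-step: posterior node weights under an N(0,1) latent density at
    ``n_nodes`` Gauss-Hermite nodes.  M-step: per-item bounded
    quasi-Newton maximisation of the expected complete-data
    log-likelihood.  Exit when ``|delta LL| < tol`` or ``max_iter``.
    Standard errors come from finite-difference observed information of
    the per-item marginal log-likelihood blocks at the solution.
    """
    X = matrix.responses
    n, K = X.shape
    if n < 2:
        raise ValueError("need at least 2 persons to calibrate")
    m = int(X.max())
    if m < 1:
        raise ValueError("all responses identical: nothing to calibrate")
    fit_warnings: list[str] = []
    for j in range(K):
        counts = np.bincount(X[:, j], minlength=m + 1)
        if (counts > 0).sum() < 2:
            raise ValueError(
                f"item {j + 1} has responses in a single category; collapse it before fitting"
            )
        if (counts == 0).any():
            fit_warnings.append(
                f"item {j + 1} has empty categories {list(np.where(counts == 0)[0])}; "
                "estimates may be unstable"
            )

    nodes, weights = _gh_nodes(n_nodes)
    params = np.array([_start_values(X[:, j], m) for j in range(K)])  # (K, 1+m)
    log_w = np.log(weights)

    # hard box plus a per-iteration trust region: items with near-degenerate
    # middle categories otherwise race to the boundary on early E-steps
    hard_lo = np.array([1e-3] + [-8.0] * m)
    hard_hi = np.array([25.0] + [8.0] * m)
    trust = 0.5
    prev_ll = -np.inf
    ll = -np.inf
    it = 0
    converged = False
    onehot = [(X == k) for k in range(m + 1)]  # list of (n, K) masks

    for it in range(1, max_iter + 1):
        logp = _log_category_matrix(params[:, 0], params[:, 1:], nodes)
        pll = _person_loglik(logp, X)  # (n, Q)
        joint = pll + log_w[None, :]
        mx = joint.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(joint - mx).sum(axis=1))
        ll = float(lse.sum())
        W = np.exp(joint - lse[:, None])  # posterior node weights (n, Q)

        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

        # expected counts r[j, q, k] = sum_i W[i, q] * 1{X[i, j] == k}
        r = np.empty((K, n_nodes, m + 1))
        for k in range(m + 1):
            r[:, :, k] = onehot[k].T @ W
        for j in range(K):
            lo = np.maximum(params[j] - trust, hard_lo)
            hi = np.minimum(params[j] + trust, hard_hi)
            res = optimize.minimize(
                _item_objective,
                params[j],
                args=(nodes, r[j], m),
                jac=True,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 50},
            )
            pj = res.x.copy()
            order = np.argsort(pj[1:])
            pj[1:] = pj[1:][order]  # re-sort transiently disordered betas
            for k in range(2, m + 1):  # keep strictly increasing
                if pj[k] <= pj[k - 1]:
                    pj[k] = pj[k - 1] + 1e-6
            params[j] = pj

    if not converged:
        fit_warnings.append(f"EM did not converge in {max_iter} iterations (|dLL|={abs(ll - prev_ll):.2e})")

    # standard errors: per-item finite-difference observed information of the
    # marginal log-likelihood (block-diagonal approximation)
    ses = np.full_like(params, np.nan)
    for j in range(K):
        ses[j] = _item_block_se(params, X, nodes, log_w, j, m)

    items = tuple(
        Item(
            id=j + 1,
            label=(labels[j] if labels else f"item_{j + 1}"),
            alpha=float(params[j, 0]),
            betas=tuple(float(b) for b in params[j, 1:]),
        )
        for j in range(K)
    )
    se_df = pd.DataFrame(
        ses, columns=["alpha"] + [f"beta{k + 1}" for k in range(m)],
        index=pd.Index(range(1, K + 1), name="item"),
    )
    return GRMFit(
        bank=ItemBank(items),
        standard_errors=se_df,
        log_likelihood=ll,
        n_iterations=it,
        converged=converged,
        quadrature_spec={"n_nodes": n_nodes, "density": "N(0,1)", "rule": "gauss-hermite"},
        warnings=fit_warnings,
    )


def _marginal_ll(params: np.ndarray, X: np.ndarray, nodes: np.ndarray, log_w: np.ndarray) -> float:
    logp = _log_category_matrix(params[:, 0], params[:, 1:], nodes)
    joint = _person_loglik(logp, X) + log_w[None, :]
    mx = joint.max(axis=1, keepdims=True)
    return float((mx[:, 0] + np.log(np.exp(joint - mx).sum(axis=1))).sum())


def _item_block_se(params, X, nodes, log_w, j, m) -> np.ndarray:
    """Finite-difference Hessian of the marginal LL in item j's parameters."""
    h = 1e-4
    p = params.copy()
    d = m + 1

    def f(delta: np.ndarray) -> float:
        p[j] = params[j] + delta
        out = _marginal_ll(p, X, nodes, log_w)
        p[j] = params[j]
        return out

    H = np.zeros((d, d))
    f0 = f(np.zeros(d))
    for a in range(d):
        ea = np.eye(d)[a] * h
        for b in range(a, d):
            eb = np.eye(d)[b] * h
            if a == b:
                H[a, a] = (f(ea) - 2 * f0 + f(-ea)) / h**2
            else:
                H[a, b] = H[b, a] = (
                    f(ea + eb) - f(ea - eb) - f(-ea + eb) + f(-ea - eb)
                ) / (4 * h**2)
    info = -H
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov)
        return np.where(var > 0, np.sqrt(np.maximum(var, 0)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(d, np.nan)


# ---------------------------------------------------------------------------
# latent trait estimation


@dataclass(frozen=True)
class ThetaEstimate:
    theta_hat: float
    se: float
    method: str
    n_items_used: int
    boundary: bool = False


def _pattern_logp(bank: ItemBank, responses: dict[int, int], grid: np.ndarray) -> np.ndarray:
    ll = np.zeros_like(grid)
    for item_id, resp in responses.items():
        probs = np.maximum(category_probabilities(bank[item_id], grid), PROB_FLOOR)
        ll += np.log(probs[..., resp])
    return ll


def estimate_theta(
    bank: ItemBank,
    responses: dict[int, int],
    method: str = "EAP",
    grid: np.ndarray | None = None,
) -> ThetaEstimate:
    """Estimate theta from a (possibly partial) response map {item_id: category}.

    EAP: posterior mean under an N(0,1) prior on an equally spaced
    61-node grid over [-4.5, 4.5]; se is the posterior sd.  MLE: bounded
    Newton-type maximisation with se = 1/sqrt(test information); flagged
    as boundary (caller should use EAP) for all-minimum / all-maximum
    patterns, whose likelihood is monotone in theta.
    """
    if not responses:
        raise ValueError("need at least one response")
    for item_id, resp in responses.items():
        if not 0 <= resp <= bank.max_category:
            raise ValueError(f"response {resp} out of range for item {item_id}")

    if method == "EAP":
        g = THETA_GRID if grid is None else np.asarray(grid, dtype=float)
        log_post = _pattern_logp(bank, responses, g) - 0.5 * g**2
        log_post -= log_post.max()
        w = np.exp(log_post)
        w /= w.sum()
        mean = float(w @ g)
        sd = float(np.sqrt(w @ (g - mean) ** 2))
        return ThetaEstimate(mean, sd, "EAP", len(responses))

    if method == "MLE":
        vals = np.array(list(responses.values()))
        boundary = bool(np.all(vals == 0) or np.all(vals == bank.max_category))
        if boundary:
            sign = 1.0 if np.all(vals == bank.max_category) else -1.0
            return ThetaEstimate(sign * np.inf, np.inf, "MLE", len(responses), boundary=True)
        res = optimize.minimize_scalar(
            lambda t: -_pattern_logp(bank, responses, np.asarray([t]))[0],
            bounds=(-6.0, 6.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(res.x)
        info = float(test_information(bank, theta, subset=list(responses)))
        return ThetaEstimate(theta, 1.0 / np.sqrt(max(info, PROB_FLOOR)), "MLE", len(responses))

    raise ValueError(f"unknown method {method!r}")


def eap_scores(bank: ItemBank, matrix: ResponseMatrix, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Vectorised EAP theta/se for every person over the full item set."""
    matrix.check_against_bank(bank)
    g = THETA_GRID if grid is None else np.asarray(grid, dtype=float)
    X = matrix.responses
    logp = _log_category_matrix(bank.alphas, bank.beta_matrix, g)  # (K, G, m+1)
    ll = _person_loglik(logp, X)  # (n, G)
    log_post = ll - 0.5 * g[None, :] ** 2
    log_post -= log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post)
    w /= w.sum(axis=1, keepdims=True)
    mean = w @ g
    sd = np.sqrt((w * (g[None, :] - mean[:, None]) ** 2).sum(axis=1))
    return pd.DataFrame({"person_id": matrix.person_ids, "theta_hat": mean, "se": sd})


def mean_theta_by_response(matrix: ResponseMatrix, fit: GRMFit | ItemBank) -> pd.DataFrame:
    """Mean EAP theta (with 95% CI) per item and response category.

    Flags an item when the CIs of adjacent categories overlap —
    the category ordering then fails to separate trait levels.  Empty
    categories are reported as missing.
    """
    bank = fit.bank if isinstance(fit, GRMFit) else fit
    scores = eap_scores(bank, matrix)["theta_hat"].to_numpy()
    rows = []
    for j, item in enumerate(bank):
        stats = []
        for k in range(bank.n_categories):
            sel = matrix.responses[:, j] == k
            nk = int(sel.sum())
            if nk == 0:
                stats.append(None)
                rows.append({"item": item.id, "category": k, "n": 0,
                             "mean_theta": np.nan, "ci_low": np.nan, "ci_high": np.nan})
                continue
            mu = float(scores[sel].mean())
            se = float(scores[sel].std(ddof=1) / np.sqrt(nk)) if nk > 1 else np.nan
            lo, hi = (mu - 1.96 * se, mu + 1.96 * se) if nk > 1 else (np.nan, np.nan)
            stats.append((lo, hi))
            rows.append({"item": item.id, "category": k, "n": nk,
                         "mean_theta": mu, "ci_low": lo, "ci_high": hi})
        overlap = False
        for a, b in zip(stats, stats[1:]):
            if a is None or b is None or np.isnan(a[1]) or np.isnan(b[0]):
                continue
            if b[0] <= a[1]:  # adjacent CIs overlap
                overlap = True
        for row in rows[-bank.n_categories:]:
            row["overlap_flag"] = overlap
    return pd.DataFrame(rows)
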