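"""Exploratory factor analysis of the questionnaire battery.

Minimum-residual (minres) extraction with promax rotation, eigenvalue-based
factor-count guidance, regression (Thurstone) factor scores, and
nonparametric group contrasts (Mann-Whitney U with Benjamini-Hochberg FDR
and rank-biserial effect sizes).

Conventions, fixed and logged rather than inferred:

* U is reported for the *first* sample (number of (x, y) pairs with x > y,
  ties counting one half).
* rank-biserial correlation RBC = 1 - 2U/(n1*n2); U = 0 (first sample
  entirely below the second) gives RBC = +1.
* FDR is the Benjamini-Hochberg step-up, applied across the full
  factor x group-pair family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

from .io_core import GROUPS

log = logging.getLogger("dysmap")


@dataclass
class EFASolution:
    n_factors: int
    loadings: np.ndarray       # p x k promax pattern
    phi: np.ndarray            # k x k factor correlations
    uniquenesses: np.ndarray   # p
    eigenvalues: np.ndarray    # p, sorted descending, of the correlation matrix
    scores: np.ndarray         # n x k regression factor scores (NaN for incomplete rows)


# ---------------------------------------------------------------------------
# correlation + factor count
# ---------------------------------------------------------------------------


def correlation_matrix(X: np.ndarray, min_complete: int = 3) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix of the battery columns."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sd = np.nanstd(X, axis=0, ddof=1)
    constant = np.flatnonzero(~(sd > 0))
    if constant.size:
        raise ValueError(f"constant columns (no variance): {constant.tolist()}")
    df = pd.DataFrame(X)
    complete = (~df.isna()).astype(int).T @ (~df.isna()).astype(int)
    if (complete.to_numpy() < min_complete).any():
        bad = np.argwhere(complete.to_numpy() < min_complete)
        raise ValueError(f"fewer than {min_complete} complete rows for column "
                         f"pairs {bad[:5].tolist()}")
    R = df.corr(method="pearson").to_numpy()  # pairwise complete
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < -1e-10:
        log.warning("pairwise-complete correlation matrix indefinite "
                    "(min eigenvalue %.3g); consider smoothing", eigmin)
    return R


def smooth_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest-ish PSD repair: clip eigenvalues at ``floor`` and renormalize."""
    w, Q = np.linalg.eigh(R)
    w = np.maximum(w, floor)
    S = Q @ np.diag(w) @ Q.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


def select_n_factors(R: np.ndarray) -> tuple[int, np.ndarray]:
    """Kaiser guidance: count of eigenvalues strictly > 1, plus the spectrum.

    The returned count is advisory; the run configuration may override it
    after scree inspection.
    """
    eigvals = np.sort(np.linalg.eigvalsh(R))[::-1]
    return int((eigvals > 1.0).sum()), eigvals


# ---------------------------------------------------------------------------
# minres extraction
# ---------------------------------------------------------------------------


def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rs = R - np.diag(psi)
    w, Q = np.linalg.eigh(Rs)
    idx = np.argsort(w)[::-1][:k]
    w_k = np.maximum(w[idx], 0.0)
    return Q[:, idx] * np.sqrt(w_k)


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    lam = _loadings_from_psi(R, psi, k)
    resid = R - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid ** 2))


def minres_factor(R: np.ndarray, k: int, max_iter: int = 1000,
                  gtol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual factoring: minimize off-diagonal SS of R - ΛΛᵀ.

    Communalities are profiled out: for a given uniqueness vector the optimal
    loadings come from the top-k eigenpairs of the reduced matrix, and the
    uniquenesses are optimized by L-BFGS-B from a squared-multiple-correlation
    start.  Returns (unrotated loadings, uniquenesses), uniquenesses defined
    as 1 - communality so the two sum to one per variable.
    """
    p = R.shape[0]
    if not (1 <= k < p):
        raise ValueError(f"need 1 <= k < {p}")
    # SMC start: 1 - 1/diag(R^-1); fall back to 0.5 for singular R
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(smooth_correlation(R)))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.005, 0.995)
    res = scipy.optimize.minimize(
        _minres_objective, psi0, args=(R, k), method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12})
    gnorm = float(np.abs(res.jac).max())
    if not res.success and gnorm > 1e-4:
        raise RuntimeError(
            f"minres did not converge: {res.message}; |grad|={gnorm:.3g}")
    lam = _loadings_from_psi(R, res.x, k)
    # sign convention: dominant direction positive per column
    signs = np.sign(lam.sum(axis=0))
    signs[signs == 0] = 1.0
    lam = lam * signs
    uniq = 1.0 - np.sum(lam ** 2, axis=1)
    return lam, uniq


# ---------------------------------------------------------------------------
# promax rotation
# ---------------------------------------------------------------------------


def promax_rotate(loadings: np.ndarray, power: float = 4.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Varimax followed by the oblique promax target transformation.

    Follows the classic recipe (Kaiser-normalized varimax, element-wise
    power-``power`` target, least-squares transformation normalized to unit
    factor variances).  Returns (pattern loadings, factor correlation Φ).
    Column signs are fixed so each factor's largest-|loading| entry is
    positive.
    """
    if power < 1:
        raise ValueError("promax power must be >= 1")
    A = np.asarray(loadings, dtype=float)
    if A.shape[1] == 1:
        B = A.copy()
        phi = np.ones((1, 1))
    else:
        h = np.sqrt(np.sum(A ** 2, axis=1))
        h = np.where(h > 0, h, 1.0)
        B, _ = rotate_factors(A / h[:, None], "varimax")
        B = B * h[:, None]
        Q = B * np.abs(B) ** (power - 1.0)     # sign(B) * |B|^power
        U, *_ = np.linalg.lstsq(B, Q, rcond=None)
        try:
            d = np.diag(np.linalg.inv(U.T @ U))
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular promax transformation") from exc
        U = U * np.sqrt(d)
        B = B @ U
        phi = np.linalg.inv(U.T @ U)
    # sign fixing
    for j in range(B.shape[1]):
        if B[np.argmax(np.abs(B[:, j])), j] < 0:
            B[:, j] = -B[:, j]
            phi[j, :] *= -1
            phi[:, j] *= -1
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    return B, phi


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------


def factor_scores(X: np.ndarray, loadings: np.ndarray, phi: np.ndarray,
                  R: np.ndarray | None = None) -> np.ndarray:
    """Regression (Thurstone) factor scores: Z R⁻¹ S with structure S = ΛΦ.

    X is standardized column-wise with its own statistics (the same used for
    the correlation matrix).  Rows with any missing cell get NaN scores.
    """
    X = np.asarray(X, dtype=float)
    if R is None:
        R = correlation_matrix(X)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    Z = (X - mu) / sd
    S = loadings @ phi
    if np.linalg.eigvalsh(R).min() < 1e-10:
        raise RuntimeError("singular correlation matrix; smooth it first "
                           "(smooth_correlation)")
    W = scipy.linalg.solve(R, S, assume_a="sym")
    scores = np.full((X.shape[0], loadings.shape[1]), np.nan)
    complete = ~np.isnan(Z).any(axis=1)
    scores[complete] = Z[complete] @ W
    return scores


def fit_efa(X: np.ndarray, k: int, power: float = 4.0) -> EFASolution:
    """Full EFA: correlation -> minres -> promax -> regression scores.

    A singular correlation matrix (e.g. fewer rows than variables) is
    eigenvalue-smoothed before scoring, with a log notice.
    """
    R = correlation_matrix(X)
    _, eigvals = select_n_factors(R)
    lam0, _ = minres_factor(R, k)
    loadings, phi = promax_rotate(lam0, power=power)
    uniq = 1.0 - np.einsum("jk,kl,jl->j", loadings, phi, loadings)
    R_score = R
    if np.linalg.eigvalsh(R).min() < 1e-10:
        log.info("correlation matrix singular; smoothing for factor scoring")
        R_score = smooth_correlation(R, floor=1e-4)
    scores = factor_scores(X, loadings, phi, R=R_score)
    return EFASolution(n_factors=k, loadings=loadings, phi=phi,
                       uniquenesses=uniq, eigenvalues=eigvals, scores=scores)


# ---------------------------------------------------------------------------
# nonparametric group contrasts
# ---------------------------------------------------------------------------


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U for the first sample with exact or tie-corrected p.

    Exact enumeration p when n1*n2 <= 400 and there are no ties; otherwise
    normal approximation with tie correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """RBC = 1 - 2U/(n1*n2) under the first-sample U convention."""
    if not (0 <= U <= n1 * n2):
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    return 1.0 - 2.0 * U / (n1 * n2)


def benjamini_hochberg(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up: (monotone adjusted p-values, rejection mask at level q)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def group_compare_factors(scores: np.ndarray, participants: pd.DataFrame,
                          q: float = 0.05) -> pd.DataFrame:
    """All pairwise group contrasts for every factor, FDR across the family."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    rows = []
    for g1, g2 in itertools.combinations(GROUPS, 2):
        a = (participants["group"] == g1).to_numpy()
        b = (participants["group"] == g2).to_numpy()
        if a.sum() < 2 or b.sum() < 2:
            raise ValueError(f"need >= 2 participants per group ({g1} vs {g2})")
        for j in range(k):
            xj = scores[a, j]
            yj = scores[b, j]
            xj, yj = xj[~np.isnan(xj)], yj[~np.isnan(yj)]
            U, p = mann_whitney_u(xj, yj)
            rows.append({"factor": j + 1, "group1": g1, "group2": g2,
                         "n1": xj.size, "n2": yj.size, "U": U, "p": p,
                         "rbc": rank_biserial(U, xj.size, yj.size)})
    table = pd.DataFrame(rows)
    table["p_fdr"], table["significant"] = benjamini_hochberg(table["p"], q)
    return table
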