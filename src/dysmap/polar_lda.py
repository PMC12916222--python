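"""Polar Latent Dirichlet Allocation over signed vertex tokens.

A topic model for deviation maps: each participant is a document, each
vertex a word, and each token additionally carries a polarity (thickening
vs thinning).  Generative story per token of participant d:

    factor  k ~ Categorical(theta_d)        theta_d ~ Dirichlet(alpha)
    vertex  v ~ Categorical(beta_k)
    sign    s ~ Bernoulli(gamma_{k, v})

Inference is mean-field variational EM: a Dirichlet variational posterior on
each theta_d, exact token-type responsibilities, and point-estimated beta and
gamma as smoothed ratios of expected counts (Dirichlet ``eta`` and symmetric
Beta ``kappa`` smoothing).  Every update is a coordinate-ascent step on one
evidence lower bound, so the bound trajectory is non-decreasing; the model
with the highest final bound over random restarts is selected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, psi, xlogy

from .deviation import SignedCounts

log = logging.getLogger("dysmap")


@dataclass
class PolarLDAModel:
    K: int
    beta: np.ndarray            # K x V, rows simplex: Pr(Vertex | Factor)
    gamma: np.ndarray           # K x V in (0,1): Pr(sign=+ | Factor, Vertex)
    theta: np.ndarray           # D x K, rows simplex: Pr(Factor | Participant)
    alpha: float
    eta: float
    kappa: float
    bound: float = -np.inf      # final evidence lower bound (nats)
    bounds: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_iter: int = 0
    converged: bool = False
    init_seed: int | None = None

    @property
    def V(self) -> int:
        return self.beta.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=atol):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.beta.sum(axis=1), 1.0, atol=atol):
            raise ValueError("beta rows must sum to 1")
        if np.any(self.gamma <= 0) or np.any(self.gamma >= 1):
            raise ValueError("gamma must lie strictly inside (0, 1)")


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def generate(model: PolarLDAModel, tokens_per_doc, seed: int = 0) -> SignedCounts:
    """Sample signed counts from the generative story (for recovery tests).

    ``tokens_per_doc`` is an int or a length-D vector of document sizes.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    D = model.theta.shape[0]
    N = np.broadcast_to(np.asarray(tokens_per_doc, dtype=int), (D,))
    npos = np.zeros((D, model.V), dtype=np.int64)
    nneg = np.zeros_like(npos)
    for d in range(D):
        nk = rng.multinomial(N[d], model.theta[d])
        for k in np.flatnonzero(nk):
            nv = rng.multinomial(nk[k], model.beta[k])
            vs = np.flatnonzero(nv)
            pos = rng.binomial(nv[vs], model.gamma[k, vs])
            npos[d, vs] += pos
            nneg[d, vs] += nv[vs] - pos
    return SignedCounts(npos=npos, nneg=nneg, ids=[f"d{d}" for d in range(D)])


# ---------------------------------------------------------------------------
# variational EM
# ---------------------------------------------------------------------------


def _elbo(npos, nneg, rpos, rneg, phi, elog_theta, beta, gamma,
          alpha, eta, kappa) -> float:
    K = beta.shape[0]
    lw_pos = np.log(beta) + np.log(gamma)        # K x V
    lw_neg = np.log(beta) + np.log1p(-gamma)
    # token term: E_q[log p(w, z)] - E_q[log q(z)]
    tok = 0.0
    for n, r, lw in ((npos, rpos, lw_pos), (nneg, rneg, lw_neg)):
        contrib = r * (elog_theta[:, None, :] + lw.T[None, :, :]) - xlogy(r, r)
        tok += float(np.sum(n[:, :, None] * contrib))
    # Dirichlet prior on theta and entropy of q(theta)
    prior = float(np.sum((alpha - 1.0) * elog_theta)) \
        + phi.shape[0] * float(gammaln(K * alpha) - K * gammaln(alpha))
    entropy = float(np.sum(gammaln(phi)) - np.sum(gammaln(phi.sum(axis=1)))
                    - np.sum((phi - 1.0) * elog_theta))
    # MAP smoothing terms for the point-estimated beta and gamma
    smooth = eta * float(np.sum(np.log(beta))) \
        + kappa * float(np.sum(np.log(gamma) + np.log1p(-gamma)))
    return tok + prior + entropy + smooth


def _responsibilities(elog_theta, beta, gamma):
    lw_pos = (np.log(beta) + np.log(gamma)).T          # V x K
    lw_neg = (np.log(beta) + np.log1p(-gamma)).T
    out = []
    for lw in (lw_pos, lw_neg):
        s = elog_theta[:, None, :] + lw[None, :, :]     # D x V x K
        s -= s.max(axis=2, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=2, keepdims=True)
        out.append(s)
    return out  # rpos, rneg


def fit_single(data: SignedCounts, K: int, *, alpha: float | None = None,
               eta: float = 0.01, kappa: float = 1.0, seed: int = 0,
               max_iter: int = 500, tol: float = 1e-6) -> PolarLDAModel:
    """One variational-EM run from a random initialization.

    The bound is evaluated after every full update sweep and must be
    non-decreasing; a non-finite bound raises with the iteration index.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    npos, nneg = data.npos.astype(float), data.nneg.astype(float)
    D, V = npos.shape
    if D == 0 or (npos + nneg).sum() == 0:
        raise ValueError("empty count data")
    if alpha is None:
        alpha = 50.0 / K
    rng = np.random.default_rng(seed)
    Nd = (npos + nneg).sum(axis=1)

    # random initialization (multi-restart selection relies on init diversity)
    beta = rng.gamma(1.0, 1.0, size=(K, V)) + 1e-8
    beta /= beta.sum(axis=1, keepdims=True)
    gamma = rng.uniform(0.3, 0.7, size=(K, V))
    phi = alpha + (Nd[:, None] / K) * rng.dirichlet(np.ones(K), size=D) * K

    bounds = []
    converged = False
    for it in range(max_iter):
        elog_theta = psi(phi) - psi(phi.sum(axis=1, keepdims=True))
        rpos, rneg = _responsibilities(elog_theta, beta, gamma)
        # variational Dirichlet update for each document
        phi = alpha + np.einsum("dv,dvk->dk", npos, rpos) \
            + np.einsum("dv,dvk->dk", nneg, rneg)
        elog_theta = psi(phi) - psi(phi.sum(axis=1, keepdims=True))
        # M-step: smoothed MAP ratios of expected counts
        epos = np.einsum("dv,dvk->kv", npos, rpos)
        eneg = np.einsum("dv,dvk->kv", nneg, rneg)
        en = epos + eneg
        beta = (en + eta) / (en.sum(axis=1, keepdims=True) + V * eta)
        gamma = (epos + kappa) / (en + 2.0 * kappa)
        b = _elbo(npos, nneg, rpos, rneg, phi, elog_theta, beta, gamma,
                  alpha, eta, kappa)
        if not np.isfinite(b):
            raise RuntimeError(f"non-finite bound at iteration {it}")
        bounds.append(b)
        if it > 0 and abs(bounds[-1] - bounds[-2]) <= tol * abs(bounds[-1]):
            converged = True
            break
    theta = phi / phi.sum(axis=1, keepdims=True)
    return PolarLDAModel(K=K, beta=beta, gamma=gamma, theta=theta,
                         alpha=alpha, eta=eta, kappa=kappa,
                         bound=bounds[-1], bounds=np.asarray(bounds),
                         n_iter=len(bounds), converged=converged,
                         init_seed=seed)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(x % (2 ** 31))
            for x in np.random.SeedSequence(int(seed)).generate_state(n)]


def fit(data: SignedCounts, K: int, n_init: int = 100, *,
        alpha: float | None = None, eta: float = 0.01, kappa: float = 1.0,
        seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
        return_all: bool = False):
    """Multi-restart fit; the run with the highest final bound wins.

    With ``return_all`` the full list of restart models is returned alongside
    the winner (used for cross-restart stability scoring).
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    models = []
    for s in _child_seeds(seed, n_init):
        try:
            models.append(fit_single(data, K, alpha=alpha, eta=eta, kappa=kappa,
                                     seed=s, max_iter=max_iter, tol=tol))
        except RuntimeError as exc:
            log.warning("restart failed: %s", exc)
    if not models:
        raise RuntimeError("all restarts failed")
    best = max(models, key=lambda m: m.bound)
    log.info("fit K=%d: best bound %.2f over %d restarts", K, best.bound, len(models))
    if return_all:
        return best, models
    return best


def select_K(data: SignedCounts, K_grid, n_init: int = 100, *,
             alpha: float | None = None, eta: float = 0.01, kappa: float = 1.0,
             seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
             n_top: int = 5) -> dict[int, dict]:
    """Fit every K in the grid and report bound plus cross-restart stability.

    Stability is the mean matched signed-map correlation between the top
    ``n_top`` restarts (by bound), pairwise.  The final K is a user decision
    confirmed via the run configuration; the report is advisory.
    """
    if not len(K_grid):
        raise ValueError("K_grid must be non-empty")
    report: dict[int, dict] = {}
    seeds = _child_seeds(seed, len(K_grid))
    for K, s in zip(K_grid, seeds):
        best, models = fit(data, K, n_init=n_init, alpha=alpha, eta=eta,
                           kappa=kappa, seed=s, max_iter=max_iter, tol=tol,
                           return_all=True)
        top = sorted(models, key=lambda m: -m.bound)[:n_top]
        corrs = []
        for a, b in itertools.combinations(top, 2):
            _, c = match_factors(signed_loading_map(a), signed_loading_map(b))
            corrs.append(float(np.mean(c)))
        report[K] = {"model": best, "bound": float(best.bound),
                     "bounds": [float(m.bound) for m in models],
                     "stability": float(np.mean(corrs)) if corrs else 1.0}
    return report


# ---------------------------------------------------------------------------
# factor maps and matching
# ---------------------------------------------------------------------------


def signed_loading_map(model: PolarLDAModel) -> np.ndarray:
    """lambda = beta * (2*gamma - 1): sign encodes thickening vs thinning,
    magnitude encodes factor relevance."""
    return model.beta * (2.0 * model.gamma - 1.0)


def match_factors(maps_a: np.ndarray, maps_b: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one factor assignment maximizing total Pearson correlation.

    Exhaustive over permutations (K <= 6).  Returns (perm, corrs) where row k
    of ``maps_a`` is matched to row ``perm[k]`` of ``maps_b``.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("map sets must have equal shapes")
    K = A.shape[0]
    if K > 6:
        raise ValueError("exhaustive matching supports K <= 6")
    C = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            sa, sb = A[i].std(), B[j].std()
            C[i, j] = (np.corrcoef(A[i], B[j])[0, 1]
                       if sa > 0 and sb > 0 else 0.0)
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(K)):
        total = sum(C[i, perm[i]] for i in range(K))
        if total > best_total:
            best_total, best_perm = total, perm
    perm = np.asarray(best_perm)
    return perm, C[np.arange(K), perm]


def theta_percent_table(model: PolarLDAModel, ids) -> "np.ndarray":
    """Factor compositions scaled to percentages (rows sum to 100)."""
    import pandas as pd
    return pd.DataFrame(model.theta * 100.0, index=list(ids),
                        columns=[f"factor{k + 1}" for k in range(model.K)])
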