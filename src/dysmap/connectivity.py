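"""Seed-to-vertex intrinsic functional connectivity with permutation cluster FWE.

Time series are cleaned by nuisance regression (six rigid-body motion
parameters and their backward-difference temporal derivatives, white matter
and cerebrospinal fluid: the 12-parameter motion model plus two tissue
signals).  Seed-to-vertex Pearson correlations are Fisher-z transformed
before group modeling.  Cluster-level familywise error is controlled by a
permutation max-cluster-size test with Freedman-Lane residual permutation
under the reduced (covariate-only) model — exact under exchangeability,
replacing parametric random-field cluster correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Mesh
from .surface_stats import Cluster, atlas_overlap, extract_clusters

MOTION_COLS = [f"mot{j}" for j in range(1, 7)]


@dataclass
class FwCluster(Cluster):
    p_fwe: float = 1.0


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------


def expand_confounds(conf: pd.DataFrame) -> np.ndarray:
    """Build the 14-regressor nuisance matrix from an 8-column confound table.

    Input columns: mot1..mot6, wm, csf.  Temporal derivatives of the motion
    parameters are backward differences with a zero first row.  A 14-column
    table is accepted as already expanded.
    """
    if conf.shape[1] == 14:
        return conf.to_numpy(dtype=float)
    missing = [c for c in MOTION_COLS + ["wm", "csf"] if c not in conf.columns]
    if missing:
        raise ValueError(f"confound table missing columns: {missing}")
    mot = conf[MOTION_COLS].to_numpy(dtype=float)
    deriv = np.diff(mot, axis=0, prepend=mot[:1])
    return np.column_stack([mot, deriv,
                            conf["wm"].to_numpy(dtype=float),
                            conf["csf"].to_numpy(dtype=float)])


def nuisance_regress(ts: np.ndarray, conf: pd.DataFrame) -> np.ndarray:
    """Residualize each vertex series on intercept + 14 nuisance regressors."""
    ts = np.asarray(ts, dtype=float)           # V x T
    T = ts.shape[1]
    if T <= 16:
        raise ValueError("need more than 16 time points for the 14-parameter model")
    C = expand_confounds(conf)
    if C.shape[0] != T:
        raise ValueError(f"confound rows ({C.shape[0]}) != time points ({T})")
    X = np.column_stack([np.ones(T), C])
    coef, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ coef).T


# ---------------------------------------------------------------------------
# seed FC
# ---------------------------------------------------------------------------


def seed_timeseries(ts: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over the ROI vertices."""
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    return np.asarray(ts, dtype=float)[roi].mean(axis=0)


def fc_map(ts: np.ndarray, seed_series: np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex Pearson r with the seed plus Fisher z (r clipped at 1-1e-7).

    Constant vertex series get r = 0 (flagged via exact zero).
    """
    ts = np.asarray(ts, dtype=float)
    s = np.asarray(seed_series, dtype=float)
    if s.std() == 0:
        raise ValueError("seed series is constant")
    sc = s - s.mean()
    tc = ts - ts.mean(axis=1, keepdims=True)
    denom = np.sqrt((tc ** 2).sum(axis=1)) * np.sqrt((sc ** 2).sum())
    ok = denom > 0
    r = np.zeros(ts.shape[0])
    r[ok] = (tc[ok] @ sc) / denom[ok]
    r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    return r, np.arctanh(r)


def fc_group_glm(zmaps: np.ndarray, participants: pd.DataFrame,
                 contrast=("ADHD_IEO", "ADHD"), covariates=("age", "sex"),
                 mask: np.ndarray | None = None):
    """Vertex-wise group GLM on Fisher-z maps (same contract as vertex_glm)."""
    from .surface_stats import vertex_glm

    return vertex_glm(zmaps, participants, contrast=contrast,
                      covariates=covariates, mask=mask)


# ---------------------------------------------------------------------------
# permutation cluster FWE
# ---------------------------------------------------------------------------


def _signed_clusters(t: np.ndarray, p: np.ndarray, cluster_p: float,
                     mesh: Mesh, keep: np.ndarray) -> list[Cluster]:
    """Clusters of supra-threshold vertices, formed separately per t sign."""
    out = []
    for sign in (1.0, -1.0):
        vs = np.flatnonzero(keep & (p < cluster_p) & (np.sign(t) == sign))
        out.extend(extract_clusters(vs, mesh, stat=t))
    out.sort(key=lambda cl: (-cl.size, cl.vertices.min()))
    return out


def cluster_fwe(zmaps: np.ndarray, participants: pd.DataFrame, contrast,
                mesh: Mesh, cluster_p: float = 0.01, n_perm: int = 1000,
                alpha: float = 0.05, seed: int = 0,
                covariates=("age", "sex"),
                exclude: np.ndarray | None = None) -> list[FwCluster]:
    """Cluster-level FWE for a pairwise group contrast on FC maps.

    The two groups in the contrast are analyzed jointly with age/sex
    covariates; the null distribution of the maximal cluster size comes from
    Freedman-Lane permutation: residuals of the reduced (covariate-only)
    model are row-permuted, the reduced fit is added back, and the full-model
    t-map is recomputed.  A cluster's corrected p is
    (1 + #{null max >= size}) / (1 + n_perm).  Seed vertices themselves can
    be excluded from inference via ``exclude``.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    zmaps = np.asarray(zmaps, dtype=float)
    V = zmaps.shape[1]
    sel = participants["group"].isin(contrast).to_numpy()
    sub = participants.loc[sel].reset_index(drop=True)
    Y = zmaps[sel]
    n = len(sub)
    g = (sub["group"] == contrast[0]).to_numpy(dtype=float)
    Z = np.column_stack([np.ones(n)]
                        + [sub[c].to_numpy(dtype=float) for c in covariates])
    X = np.column_stack([Z, g])
    cvec = np.zeros(X.shape[1])
    cvec[-1] = 1.0
    keep = np.ones(V, dtype=bool)
    if exclude is not None:
        keep[np.asarray(exclude, dtype=int)] = False

    from .surface_stats import _glm_tmap

    t_obs, p_obs = _glm_tmap(Y, X, cvec)
    observed = _signed_clusters(t_obs, p_obs, cluster_p, mesh, keep)

    # Freedman-Lane: permute reduced-model residuals
    Hz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    fitted = Hz @ Y
    resid = Y - fitted
    rng = np.random.default_rng(seed)
    max_null = np.zeros(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = fitted + resid[perm]
        tb, pb = _glm_tmap(Yb, X, cvec)
        cl = _signed_clusters(tb, pb, cluster_p, mesh, keep)
        max_null[b] = cl[0].size if cl else 0
    out = []
    for c in observed:
        p_fwe = (1.0 + float((max_null >= c.size).sum())) / (1.0 + n_perm)
        out.append(FwCluster(vertices=c.vertices, size=c.size,
                             peak_stat=c.peak_stat, mean_stat=c.mean_stat,
                             p_fwe=p_fwe))
    return out


def network_profile(clusters, atlas: np.ndarray) -> dict[int, float]:
    """Network membership percentages for the union of cluster vertices."""
    if not clusters:
        raise ValueError("no clusters to profile")
    union = np.unique(np.concatenate([c.vertices for c in clusters]))
    return atlas_overlap(union, atlas)
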