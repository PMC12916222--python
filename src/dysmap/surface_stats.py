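"""Conjunction mapping, vertex-wise group GLMs, clusters and atlas profiling.

The conjunction map sums absolute signed factor loadings across all latent
brain factors, highlighting vertices deviating under any factor.  Group
differences in CT are tested vertex-wise with an OLS model (intercept +
group indicators + age + sex), FDR-corrected, and surviving vertices are
split into connected clusters under the mesh adjacency; the largest cluster
serves as the seed ROI for connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
import scipy.stats

from .io_core import GROUPS, Mesh


@dataclass
class Cluster:
    vertices: np.ndarray     # sorted vertex indices, connected under the mesh
    size: int
    peak_stat: float
    mean_stat: float


# ---------------------------------------------------------------------------
# conjunction
# ---------------------------------------------------------------------------


def conjunction_map(lam: np.ndarray) -> np.ndarray:
    """c_v = sum_k |lambda_{k,v}| over all latent factors."""
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    return np.abs(lam).sum(axis=0)


def threshold_mask(c: np.ndarray, percentile: float) -> np.ndarray:
    """Boolean mask of vertices at or above the given percentile of c."""
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    c = np.asarray(c, dtype=float)
    if np.ptp(c) == 0:
        raise ValueError("degenerate (all-equal) conjunction map")
    thr = np.percentile(c, percentile)
    return c >= thr


# ---------------------------------------------------------------------------
# vertex-wise GLM
# ---------------------------------------------------------------------------


def _group_design(participants: pd.DataFrame, covariates=("age", "sex")):
    """Design matrix [1 | dummies for present groups (first = reference) | covariates]."""
    n = len(participants)
    present = [g for g in GROUPS if (participants["group"] == g).any()]
    cols = [np.ones(n)]
    names = ["intercept"]
    for g in present[1:]:
        cols.append((participants["group"] == g).to_numpy(dtype=float))
        names.append(g)
    for c in covariates:
        cols.append(participants[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names, present[0]


def _contrast_vector(names, reference, contrast) -> np.ndarray:
    ga, gb = contrast
    c = np.zeros(len(names))
    for g, sign in ((ga, 1.0), (gb, -1.0)):
        if g != reference:
            if g not in names:
                raise ValueError(f"group {g!r} absent from the design")
            c[names.index(g)] += sign
    return c


def _glm_tmap(Y: np.ndarray, X: np.ndarray, c: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS t-statistics for contrast c over columns of Y."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient GLM design")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y                    # p x V
    resid = Y - X @ B
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    var_c = float(c @ XtX_inv @ c)
    denom = np.sqrt(np.maximum(sigma2 * var_c, 1e-300))
    t = (c @ B) / denom
    p_two = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    return t, p_two


def vertex_glm(data: np.ndarray, participants: pd.DataFrame,
               contrast=("ADHD_IEO", "NT"), covariates=("age", "sex"),
               mask: np.ndarray | None = None,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex t and two-sided p for a pairwise group contrast.

    ``data`` is participants x vertices (CT or FC).  Vertices outside
    ``mask`` get NaN.  Contrast of a group with itself gives t = 0.
    """
    data = np.asarray(data, dtype=float)
    V = data.shape[1]
    X, names, ref = _group_design(participants, covariates)
    if contrast[0] == contrast[1]:
        t = np.zeros(V)
        p = np.ones(V)
    else:
        cvec = _contrast_vector(names, ref, contrast)
        t, p = _glm_tmap(data, X, cvec)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty vertex mask")
        t = np.where(mask, t, np.nan)
        p = np.where(mask, p, np.nan)
    return t, p


def fdr_select(pmap: np.ndarray, q: float = 0.05,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg over (masked) vertices; returns surviving indices."""
    from .efa import benjamini_hochberg

    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    pmap = np.asarray(pmap, dtype=float)
    idx = (np.flatnonzero(np.asarray(mask, dtype=bool)) if mask is not None
           else np.flatnonzero(~np.isnan(pmap)))
    if idx.size == 0:
        return idx
    _, reject = benjamini_hochberg(pmap[idx], q)
    return idx[reject]


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


def extract_clusters(vertices: np.ndarray, mesh: Mesh,
                     stat: np.ndarray | None = None) -> list[Cluster]:
    """Connected components of a vertex set under the mesh adjacency.

    Sorted by size descending; ties broken by lowest minimum vertex index.
    The first cluster is the seed ROI.  An empty input yields an empty list.
    """
    vertices = np.asarray(vertices, dtype=int)
    if vertices.size == 0:
        return []
    sub = mesh.adjacency[vertices][:, vertices]
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    clusters = []
    for comp in range(n_comp):
        vs = np.sort(vertices[labels == comp])
        if stat is not None:
            s = np.asarray(stat, dtype=float)[vs]
            peak = float(s[np.argmax(np.abs(s))])
            mean = float(s.mean())
        else:
            peak = mean = np.nan
        clusters.append(Cluster(vertices=vs, size=vs.size,
                                peak_stat=peak, mean_stat=mean))
    clusters.sort(key=lambda cl: (-cl.size, cl.vertices.min()))
    return clusters


def seed_roi(clusters: list[Cluster]) -> np.ndarray:
    if not clusters:
        raise ValueError("cannot extract an ROI from an empty cluster set")
    return clusters[0].vertices


# ---------------------------------------------------------------------------
# effect size and atlas overlap
# ---------------------------------------------------------------------------


def cohens_d(data: np.ndarray, participants: pd.DataFrame, roi: np.ndarray,
             pair=("ADHD_IEO", "NT")) -> float:
    """Cohen's d of ROI-mean values between two groups (pooled SD)."""
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    vals = np.asarray(data, dtype=float)[:, roi].mean(axis=1)
    a = vals[(participants["group"] == pair[0]).to_numpy()]
    b = vals[(participants["group"] == pair[1]).to_numpy()]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 participants per group")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def atlas_overlap(roi: np.ndarray, atlas: np.ndarray) -> dict[int, float]:
    """Percentage of ROI vertices in each network; sums to 100."""
    roi = np.asarray(roi, dtype=int)
    atlas = np.asarray(atlas, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    labels = atlas[roi]
    if (labels < 1).any():
        raise ValueError(f"unlabeled ROI vertices: {roi[labels < 1].tolist()}")
    out = {}
    for net in range(1, atlas.max() + 1):
        out[net] = 100.0 * float((labels == net).sum()) / roi.size
    return out
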