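"""Brain-behavior linear regressions.

Each latent behavioral factor score is regressed on a brain scalar (ROI-mean
CT or cluster-mean FC) plus age and sex; the brain coefficient's estimate,
SE, t and two-sided p are reported per factor.  No multiple-testing
correction across factors by default (an optional BH flag adds it); both the
raw-unit and standardized-predictor slopes are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm


def roi_mean(data: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Unweighted mean over ROI vertices, per participant."""
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    return np.asarray(data, dtype=float)[:, roi].mean(axis=1)


def brain_behavior_regression(scores: np.ndarray, brain_scalar: np.ndarray,
                              participants: pd.DataFrame, factors=None,
                              fdr: bool = False) -> pd.DataFrame:
    """OLS of each factor score on intercept + brain scalar + age + sex.

    Returns a tidy table with the brain-scalar coefficient per factor
    (beta, SE, t, p, n, and a standardized beta), flagging p < 0.05.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and len(participants) != 1:
        scores = scores.T
    brain = np.asarray(brain_scalar, dtype=float)
    k = scores.shape[1]
    if factors is None:
        factors = range(1, k + 1)
    X = np.column_stack([brain,
                         participants["age"].to_numpy(dtype=float),
                         participants["sex"].to_numpy(dtype=float)])
    rows = []
    for f in factors:
        y = scores[:, f - 1]
        ok = ~(np.isnan(y) | np.isnan(brain))
        if ok.sum() < 5:
            raise ValueError(f"fewer than 5 complete cases for factor {f}")
        Xf = sm.add_constant(X[ok])
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise ValueError("collinear design in brain-behavior regression")
        fit = sm.OLS(y[ok], Xf).fit()
        beta, se = fit.params[1], fit.bse[1]
        rows.append({
            "factor": f, "predictor": "brain", "beta": beta, "se": se,
            "t": fit.tvalues[1], "p": fit.pvalues[1], "n": int(ok.sum()),
            "beta_std": beta * np.std(brain[ok], ddof=1)
            / np.std(y[ok], ddof=1),
        })
    out = pd.DataFrame(rows)
    if fdr:
        from .efa import benjamini_hochberg
        out["p_fdr"], out["significant"] = benjamini_hochberg(out["p"], 0.05)
    else:
        out["significant"] = out["p"] < 0.05
    return out
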