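"""NT-referenced deviation maps and their signed count encoding.

Raw CT matrices are confound-residualized (OLS on intercept + age + sex +
motion, fit on the NT group only so patient deviation signal never enters the
nuisance fit, then applied to everyone), z-scored against the NT reference
(sample SD, ddof=1), and finally discretized into the signed token counts the
polar topic model consumes: ``n+ = round(C * max(z, 0))`` and
``n- = round(C * max(-z, 0))`` after clipping |z| at ``z_cap``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("dysmap")


@dataclass
class DeviationMap:
    """Patients x vertices z-scores plus the NT reference statistics."""

    z: np.ndarray
    patient_idx: np.ndarray      # row indices into the participants table
    ref_mean: np.ndarray         # V
    ref_sd: np.ndarray           # V


@dataclass
class SignedCounts:
    """Signed token counts per participant (document) and vertex (word)."""

    npos: np.ndarray             # D x V non-negative ints
    nneg: np.ndarray             # D x V non-negative ints
    ids: list[str]

    def __post_init__(self):
        if self.npos.shape != self.nneg.shape:
            raise ValueError("npos/nneg shape mismatch")
        if (self.npos < 0).any() or (self.nneg < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def D(self) -> int:
        return self.npos.shape[0]

    @property
    def V(self) -> int:
        return self.npos.shape[1]

    @property
    def total(self) -> np.ndarray:
        """Tokens per document N_d."""
        return (self.npos + self.nneg).sum(axis=1)

    def to_triplets(self) -> pd.DataFrame:
        d, v = np.nonzero(self.npos + self.nneg)
        return pd.DataFrame({"participant": [self.ids[i] for i in d],
                             "vertex": v,
                             "n_pos": self.npos[d, v],
                             "n_neg": self.nneg[d, v]})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# signed token counts, V={self.V} (0-based vertices)\n")
            self.to_triplets().to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "SignedCounts":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        V = int(header.split("V=")[1].split()[0])
        ids = list(dict.fromkeys(df["participant"]))
        row = {p: i for i, p in enumerate(ids)}
        npos = np.zeros((len(ids), V), dtype=np.int64)
        nneg = np.zeros_like(npos)
        r = df["participant"].map(row).to_numpy()
        npos[r, df["vertex"]] = df["n_pos"]
        nneg[r, df["vertex"]] = df["n_neg"]
        return cls(npos=npos, nneg=nneg, ids=ids)


# ---------------------------------------------------------------------------


def residualize_confounds(ct: np.ndarray, participants: pd.DataFrame,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex OLS of CT on intercept + age + sex + motion, NT-fit.

    Coefficients are estimated on NT participants only and the predicted
    nuisance component is subtracted from every participant.  Returns
    (residual CT, 4 x V coefficient matrix) for audit.
    """
    ct = np.asarray(ct, dtype=float)
    if np.isnan(ct).any():
        raise ValueError("CT matrix contains missing values")
    X = np.column_stack([np.ones(len(participants)),
                         participants["age"].to_numpy(dtype=float),
                         participants["sex"].to_numpy(dtype=float),
                         participants["motion"].to_numpy(dtype=float)])
    nt = (participants["group"] == "NT").to_numpy()
    Xnt = X[nt]
    if np.linalg.matrix_rank(Xnt) < X.shape[1]:
        raise ValueError("rank-deficient confound design on the NT group")
    coef, *_ = np.linalg.lstsq(Xnt, ct[nt], rcond=None)
    return ct - X @ coef, coef


def zscore_vs_reference(ct_resid: np.ndarray, participants: pd.DataFrame,
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """z-score every patient's CT against the NT per-vertex mean and sample SD.

    Returns (patients x V z matrix, patient row indices, reference stats).
    NT rows are excluded from the output.
    """
    ct_resid = np.asarray(ct_resid, dtype=float)
    nt = (participants["group"] == "NT").to_numpy()
    if nt.sum() < 3:
        raise ValueError("need >= 3 NT participants for the reference")
    mean = ct_resid[nt].mean(axis=0)
    sd = ct_resid[nt].std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero NT SD at vertices {zero[:10].tolist()}")
    patient_idx = np.flatnonzero(~nt)
    z = (ct_resid[patient_idx] - mean) / sd
    return z, patient_idx, {"mean": mean, "sd": sd, "sd_ddof": 1}


def deviation_map(ct: np.ndarray, participants: pd.DataFrame) -> DeviationMap:
    """Convenience: residualize then z-score in one call."""
    resid, _ = residualize_confounds(ct, participants)
    z, idx, ref = zscore_vs_reference(resid, participants)
    return DeviationMap(z=z, patient_idx=idx, ref_mean=ref["mean"], ref_sd=ref["sd"])


def encode_signed_counts(z: np.ndarray, C: float = 10.0, z_cap: float = 4.0,
                         ids: list[str] | None = None) -> SignedCounts:
    """Discretize a z-deviation map into signed token counts.

    Positive z becomes positive tokens, negative z negative tokens; exactly
    one of the two is non-zero at each (participant, vertex).  Participants
    with no tokens at all are dropped with a warning.
    """
    if C <= 0 or z_cap <= 0:
        raise ValueError("C and z_cap must be positive")
    z = np.clip(np.asarray(z, dtype=float), -z_cap, z_cap)
    npos = np.rint(C * np.maximum(z, 0.0)).astype(np.int64)
    nneg = np.rint(C * np.maximum(-z, 0.0)).astype(np.int64)
    if ids is None:
        ids = [f"d{i}" for i in range(z.shape[0])]
    keep = (npos + nneg).sum(axis=1) > 0
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping participants with empty documents: {dropped}")
        log.warning("dropped empty documents: %s", dropped)
    if not keep.any():
        raise ValueError("all participants produced empty documents")
    return SignedCounts(npos=npos[keep], nneg=nneg[keep],
                        ids=[ids[i] for i in np.flatnonzero(keep)])
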