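"""Readers/writers, run configuration, seed management and pipeline orchestration.

All tabular data travel as pandas DataFrames read from/written to delimited
text.  Vertex indices are 0-based everywhere.  A single integer seed expands
deterministically into per-stage child seeds so any stage can be rerun in
isolation and the full pipeline is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

log = logging.getLogger("dysmap")

GROUPS = ("NT", "ADHD", "ADHD_IEO")

#: pipeline stages in execution order; seed expansion is keyed on this list
STAGES = ("simulate", "efa", "deviation", "lda", "conjunction", "fc", "brainbehavior")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mesh:
    """A cortical-surface stand-in: vertices plus a symmetric edge relation.

    ``edges`` holds each undirected edge once as (i, j) with i < j.
    """

    n_vertices: int
    edges: np.ndarray
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.int64)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("mesh contains self-edges")
        if e.size and (e.min() < 0 or e.max() >= self.n_vertices):
            raise ValueError("edge vertex index out of range")
        object.__setattr__(self, "edges", np.unique(np.sort(e, axis=1), axis=0))

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency (boolean)."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        row = np.concatenate([i, j])
        col = np.concatenate([j, i])
        data = np.ones(row.size, dtype=bool)
        return sp.csr_matrix((data, (row, col)),
                             shape=(self.n_vertices, self.n_vertices))

    def save(self, path) -> None:
        df = pd.DataFrame(self.edges, columns=["v1", "v2"])
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# mesh n_vertices={self.n_vertices} "
                     f"grid={self.grid_shape} (0-based vertex indices)\n")
            df.to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "Mesh":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        n = int(header.split("n_vertices=")[1].split()[0])
        return cls(n_vertices=n, edges=df[["v1", "v2"]].to_numpy())


def validate_participants(df: pd.DataFrame, require_all_groups: bool = False) -> pd.DataFrame:
    """Check the participants table invariants; returns the table unchanged."""
    required = {"id", "group", "age", "sex", "motion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    if require_all_groups:
        empty = [g for g in GROUPS if (df["group"] == g).sum() == 0]
        if empty:
            raise ValueError(f"group-contrast operations need all groups non-empty; "
                             f"empty: {empty}")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable pipeline settings with their defaults.

    Defaults mirror the analysis conditions: K grid {2,3,4}, 100 random
    restarts with bound-based selection, FDR q = 0.05 for vertex maps and
    cluster FWE alpha = 0.05 for connectivity.
    """

    seed: int = 0
    K_grid: list[int] = field(default_factory=lambda: [2, 3, 4])
    n_init: int = 100
    #: Dirichlet concentration on participant compositions; None -> 50/K
    alpha: float | None = None
    #: Dirichlet smoothing on vertex distributions
    eta: float = 0.01
    #: Beta smoothing on polarity probabilities
    kappa: float = 1.0
    #: tokens per unit |z| when discretizing deviation maps
    count_scale: float = 10.0
    #: |z| clipping bound before discretization
    z_cap: float = 4.0
    fdr_q: float = 0.05
    #: cluster-forming two-sided p threshold
    cluster_p: float = 0.01
    #: cluster-level FWE alpha
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    conjunction_percentile: float = 75.0
    promax_power: float = 4.0
    max_iter: int = 500
    tol: float = 1e-6
    #: None -> use eigenvalue>1 recommendation
    n_factors: int | None = None
    #: restrict the CT group GLM to the conjunction mask instead of whole brain
    use_conjunction_mask: bool = False

    _RANGES = {
        "n_init": (1, None),
        "eta": (0.0, None, "exclusive"),
        "kappa": (0.0, None, "exclusive"),
        "count_scale": (0.0, None, "exclusive"),
        "z_cap": (0.0, None, "exclusive"),
        "fdr_q": (0.0, 1.0, "exclusive"),
        "cluster_p": (0.0, 1.0, "exclusive"),
        "cluster_alpha": (0.0, 1.0, "exclusive"),
        "n_perm": (1, None),
        "conjunction_percentile": (0.0, 100.0, "exclusive"),
        "promax_power": (1.0, None),
        "max_iter": (1, None),
        "tol": (0.0, None, "exclusive"),
    }

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, rng in self._RANGES.items():
            lo, hi = rng[0], rng[1]
            exclusive = len(rng) > 2
            v = getattr(self, name)
            ok = (v > lo if exclusive else v >= lo)
            if hi is not None:
                ok = ok and (v < hi if exclusive else v <= hi)
            if not ok:
                op = "(" if exclusive else "["
                cl = ")" if exclusive else "]"
                hi_s = "inf" if hi is None else hi
                raise ValueError(
                    f"config field {name}={v!r} outside legal range "
                    f"{op}{lo}, {hi_s}{cl}")
        if not self.K_grid or any(k < 1 for k in self.K_grid):
            raise ValueError("config field K_grid must be non-empty positive integers")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("config field alpha must be positive or null (-> 50/K)")

    def alpha_for(self, K: int) -> float:
        return self.alpha if self.alpha is not None else 50.0 / K

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML/JSON config; unspecified fields take documented defaults.

    The fully resolved configuration is logged.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    unknown = set(raw) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**raw)
    log.info("resolved config: %s", cfg.to_dict())
    return cfg


# ---------------------------------------------------------------------------
# seed management
# ---------------------------------------------------------------------------

def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2 ** 31))


def stage_seeds(seed: int) -> dict[str, int]:
    return {s: stage_seed(seed, s) for s in STAGES}


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(path, rows_are_participants: bool = True,
                participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a labeled numeric matrix from delimited text.

    Missing cells (empty or ``NA``) become NaN — flagged, never zeroed.  If a
    participants table is supplied the row labels are re-ordered to match its
    ids; ids missing on either side raise a labeled error.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     na_values=["NA", "nan", ""])
    df.index = df.index.astype(str)
    if not rows_are_participants:
        df = df.T
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric cells in columns {non_numeric} of {path}")
    if participants is not None:
        want = participants["id"].astype(str).tolist()
        missing = sorted(set(want) - set(df.index))
        extra = sorted(set(df.index) - set(want))
        if missing or extra:
            raise ValueError(
                f"matrix {path} row labels do not match participants table; "
                f"missing ids: {missing}; unexpected ids: {extra}")
        df = df.loc[want]
    return df


def write_matrix(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a labeled matrix as delimited text (inverse of :func:`read_matrix`)."""
    path = pathlib.Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep, float_format="%.17g")


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    return validate_participants(df)


def write_participants(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# participants: id,group,age,sex,motion\n")
        df.to_csv(fh, index=False)


def read_atlas(path) -> np.ndarray:
    """Read a vertex -> network label vector (one integer per line, 0-based vertices)."""
    labels = pd.read_csv(path, comment="#")["network"].to_numpy()
    if labels.min() < 1:
        raise ValueError("atlas labels must be >= 1")
    return labels.astype(int)


def write_atlas(labels: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("# atlas: network label per vertex, row i = vertex i (0-based)\n")
        pd.DataFrame({"network": labels}).to_csv(fh, index=False)


# optional GIFTI adapter -----------------------------------------------------

def read_gifti_map(path) -> np.ndarray:
    """Read a per-vertex data array from a GIFTI file (optional adapter)."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("GIFTI support requires nibabel") from exc
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, data_dir, out_dir) -> dict:
    """Run every analysis stage on a cohort directory and write a JSON report.

    Expects the file layout written by :func:`dysmap.synthetic.write_cohort`:
    ``participants.csv``, ``behavior.csv``, ``ct.csv``, ``atlas.csv``,
    ``mesh.csv`` and per-participant time series under ``ts/``.  Re-running
    with the same config and inputs reproduces all stochastic outputs
    bit-identically.
    """
    from . import brain_behavior as bb
    from . import connectivity as fcmod
    from . import deviation as dev
    from . import efa as efamod
    from . import polar_lda as lda
    from . import surface_stats as ss

    data_dir = pathlib.Path(data_dir)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stage_seeds": seeds,
                    "config": config.to_dict(), "stages": {}}

    def require(name):
        p = data_dir / name
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline input: {p}")
        return p

    def run_stage(name, fn):
        try:
            report["stages"][name] = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    participants = read_participants(require("participants.csv"))
    mesh = Mesh.load(require("mesh.csv"))
    atlas = read_atlas(require("atlas.csv"))
    behavior = read_matrix(require("behavior.csv"), participants=participants)
    ct = read_matrix(require("ct.csv"), participants=participants)

    # ---- behavioral EFA ---------------------------------------------------
    state: dict = {}

    def _efa():
        corr = efamod.correlation_matrix(behavior.to_numpy())
        k_rec, eigvals = efamod.select_n_factors(corr)
        k = config.n_factors or k_rec
        sol = efamod.fit_efa(behavior.to_numpy(), k, power=config.promax_power)
        contrasts = efamod.group_compare_factors(sol.scores, participants, config.fdr_q)
        cols = [f"factor{j + 1}" for j in range(k)]
        write_matrix(pd.DataFrame(sol.loadings, index=behavior.columns, columns=cols),
                     out_dir / "efa_loadings.csv", "promax pattern loadings")
        write_matrix(pd.DataFrame(sol.phi, index=cols, columns=cols),
                     out_dir / "efa_phi.csv", "factor correlations")
        write_matrix(pd.DataFrame(sol.scores, index=participants["id"], columns=cols),
                     out_dir / "efa_scores.csv", "regression factor scores")
        contrasts.to_csv(out_dir / "efa_contrasts.csv", index=False)
        state["scores"] = sol.scores
        return {"n_factors": k, "recommended": k_rec,
                "eigenvalues_gt1": int((eigvals > 1).sum())}

    run_stage("efa", _efa)

    # ---- deviation encoding + polar LDA -----------------------------------
    def _deviation():
        resid, _ = dev.residualize_confounds(ct.to_numpy(), participants)
        zmap, patient_idx, ref = dev.zscore_vs_reference(resid, participants)
        counts = dev.encode_signed_counts(
            zmap, C=config.count_scale, z_cap=config.z_cap,
            ids=[participants["id"].iloc[i] for i in patient_idx])
        state["counts"] = counts
        state["patient_idx"] = patient_idx
        return {"n_patients": len(counts.ids),
                "total_tokens": int(counts.total.sum())}

    run_stage("deviation", _deviation)

    def _lda():
        counts = state["counts"]
        selection = lda.select_K(counts, config.K_grid, n_init=config.n_init,
                                 alpha=config.alpha, eta=config.eta,
                                 kappa=config.kappa, seed=seeds["lda"],
                                 max_iter=config.max_iter, tol=config.tol)
        best_K = max(selection, key=lambda K: selection[K]["stability"])
        model = selection[best_K]["model"]
        lam = lda.signed_loading_map(model)
        kcols = [f"factor{j + 1}" for j in range(model.K)]
        write_matrix(pd.DataFrame(model.theta * 100.0, index=counts.ids, columns=kcols),
                     out_dir / "lda_theta_percent.csv",
                     "Pr(Factor|Participant) x100; rows sum to 100")
        write_matrix(pd.DataFrame(model.beta, index=kcols,
                                  columns=[f"v{v}" for v in range(model.V)]),
                     out_dir / "lda_beta.csv", "Pr(Vertex|Factor)")
        write_matrix(pd.DataFrame(lam, index=kcols,
                                  columns=[f"v{v}" for v in range(model.V)]),
                     out_dir / "lda_lambda.csv", "signed loading maps beta*(2*gamma-1)")
        state["model"] = model
        state["lambda"] = lam
        return {"K": int(best_K),
                "bound": float(model.bound),
                "stability": {int(K): selection[K]["stability"] for K in selection}}

    run_stage("lda", _lda)

    # ---- conjunction + CT group GLM ---------------------------------------
    def _conjunction():
        conj = ss.conjunction_map(state["lambda"])
        mask = (ss.threshold_mask(conj, config.conjunction_percentile)
                if config.use_conjunction_mask else None)
        t, p = ss.vertex_glm(ct.to_numpy(), participants,
                             contrast=("ADHD_IEO", "NT"), mask=mask)
        sig = ss.fdr_select(p, config.fdr_q, mask=mask)
        clusters = ss.extract_clusters(sig, mesh, stat=t)
        pd.DataFrame({"conjunction": conj}).to_csv(out_dir / "conjunction.csv",
                                                   index_label="vertex")
        pd.DataFrame({"t": t, "p": p}).to_csv(out_dir / "ct_glm.csv",
                                              index_label="vertex")
        out = {"n_significant_vertices": int(len(sig)),
               "n_clusters": len(clusters)}
        if clusters:
            roi = clusters[0].vertices
            state["roi"] = roi
            np.savetxt(out_dir / "roi_vertices.csv", roi, fmt="%d",
                       header="seed ROI vertex indices (0-based)")
            out["roi_size"] = int(roi.size)
            out["roi_overlap"] = ss.atlas_overlap(roi, atlas)
            resid, _ = dev.residualize_confounds(ct.to_numpy(), participants)
            out["cohens_d"] = ss.cohens_d(resid, participants, roi,
                                          ("ADHD_IEO", "NT"))
        return out

    run_stage("conjunction", _conjunction)

    # ---- seed connectivity -------------------------------------------------
    def _fc():
        if "roi" not in state:
            return {"skipped": "no significant CT cluster to seed from"}
        roi = state["roi"]
        zmaps = []
        for pid in participants["id"]:
            ts = read_matrix(require(f"ts/{pid}.csv"),
                             rows_are_participants=False).to_numpy()  # V x T
            conf = pd.read_csv(data_dir / "confounds" / f"{pid}.csv", comment="#")
            cleaned = fcmod.nuisance_regress(ts, conf)
            seed_series = fcmod.seed_timeseries(cleaned, roi)
            _, z = fcmod.fc_map(cleaned, seed_series)
            zmaps.append(z)
        zmaps = np.asarray(zmaps)
        write_matrix(pd.DataFrame(zmaps, index=participants["id"],
                                  columns=[f"v{v}" for v in range(zmaps.shape[1])]),
                     out_dir / "fc_zmaps.csv", "Fisher-z seed-to-vertex iFC")
        clusters = fcmod.cluster_fwe(
            zmaps, participants, ("ADHD_IEO", "ADHD"), mesh,
            cluster_p=config.cluster_p, n_perm=config.n_perm,
            alpha=config.cluster_alpha, seed=seeds["fc"], exclude=roi)
        sig = [c for c in clusters if c.p_fwe <= config.cluster_alpha]
        out = {"n_clusters": len(clusters), "n_significant": len(sig)}
        if sig:
            union = np.concatenate([c.vertices for c in sig])
            state["fc_cluster"] = union
            out["network_profile"] = fcmod.network_profile(sig, atlas)
            out["cluster_mean_fc"] = float(zmaps[:, union].mean())
        pd.DataFrame([{"size": c.size, "p_fwe": c.p_fwe, "peak_t": c.peak_stat}
                      for c in clusters]).to_csv(out_dir / "fc_clusters.csv",
                                                 index=False)
        state["zmaps"] = zmaps
        return out

    run_stage("fc", _fc)

    # ---- brain-behavior regressions ----------------------------------------
    def _bb():
        out = {}
        if "roi" in state:
            scalar = bb.roi_mean(ct.to_numpy(), state["roi"])
            res = bb.brain_behavior_regression(state["scores"], scalar, participants)
            res.to_csv(out_dir / "brainbehavior_ct.csv", index=False)
            out["ct"] = {"n_significant": int((res["p"] < 0.05).sum())}
        if "fc_cluster" in state:
            scalar = bb.roi_mean(state["zmaps"], state["fc_cluster"])
            res = bb.brain_behavior_regression(state["scores"], scalar, participants)
            res.to_csv(out_dir / "brainbehavior_fc.csv", index=False)
            out["fc"] = {"n_significant": int((res["p"] < 0.05).sum())}
        return out

    run_stage("brainbehavior", _bb)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
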