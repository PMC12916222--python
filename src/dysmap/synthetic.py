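"""Synthetic cohort generator with planted ground truth.

Every downstream stage gets a parameter-recovery test from this module:

* a torus-grid mesh standing in for a template cortical surface, parcelled
  into contiguous "network" patches;
* a three-group participants table (NT, ADHD, ADHD_IEO) with age, sex and
  head-motion covariates;
* a 31-subscale questionnaire battery generated from a planted 4-factor
  common-factor model (Externalizing, Emotion dysregulation, Internalizing,
  Surgency/Impulsivity) with group mean shifts;
* a cortical-thickness matrix whose patient deviations are Dirichlet-weighted
  mixtures of K planted signed factor maps (thinning/thickening patches);
* resting-state-like vertex time series with per-group seed-to-network
  coupling and motion/WM/CSF leakage, plus the confound tables.

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GROUPS, Mesh

# ---------------------------------------------------------------------------
# mesh + atlas
# ---------------------------------------------------------------------------


def _grid_shape(n_vertices: int) -> tuple[int, int]:
    # largest divisor <= sqrt(V) as column count; degenerates to a cycle for primes
    cols = 1
    for c in range(int(math.isqrt(n_vertices)), 0, -1):
        if n_vertices % c == 0:
            cols = c
            break
    return n_vertices // cols, cols


def make_mesh(n_vertices: int, n_networks: int, seed: int = 0) -> tuple[Mesh, np.ndarray]:
    """Build a wraparound grid mesh and a contiguous network parcellation.

    The mesh is a torus (4-neighbour grid with wraparound in both directions),
    so it is connected and has no boundary effects.  Networks are consecutive
    chunks of the row-major vertex order, which are connected patches on the
    grid.  Labels run 1..n_networks.  ``seed`` is accepted for interface
    uniformity; the construction is deterministic.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if n_vertices < 10 * n_networks:
        raise ValueError("need n_vertices >= 10 * n_networks")
    rows, cols = _grid_shape(n_vertices)
    v = np.arange(n_vertices).reshape(rows, cols)
    edges = []
    right = np.stack([v, np.roll(v, -1, axis=1)], axis=-1).reshape(-1, 2)
    down = np.stack([v, np.roll(v, -1, axis=0)], axis=-1).reshape(-1, 2)
    edges = np.concatenate([right, down])
    edges = edges[edges[:, 0] != edges[:, 1]]  # cols==1 or rows==1 wrap to self
    mesh = Mesh(n_vertices=n_vertices, edges=edges, grid_shape=(rows, cols))
    # near-equal contiguous chunks
    bounds = np.linspace(0, n_vertices, n_networks + 1).round().astype(int)
    labels = np.zeros(n_vertices, dtype=int)
    for k in range(n_networks):
        labels[bounds[k]:bounds[k + 1]] = k + 1
    return mesh, labels


def smooth_field(mesh: Mesh, rng: np.random.Generator, n_pass: int = 4) -> np.ndarray:
    """Spatially smoothed Gaussian random field on the mesh (unit-ish scale)."""
    A = mesh.adjacency.astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    x = rng.normal(size=mesh.n_vertices)
    for _ in range(n_pass):
        x = 0.5 * x + 0.5 * (A @ x) / np.maximum(deg, 1)
    return x / x.std()


def make_factor_maps(mesh: Mesh, K: int, seed: int, sparsity: float = 0.2,
                     max_corr: float = 0.3, plateau_floor: float = 0.8,
                     ) -> np.ndarray:
    """K signed factor maps in [-1, 1]: sparse thinning/thickening patches.

    Each factor claims the top ``sparsity`` fraction of |value| of a smoothed
    random field among vertices not already claimed, so the factors occupy
    disjoint cortical territory (mirroring latent factors with
    non-overlapping thinning/thickening/mixed patterns).  Patch magnitudes
    are rescaled into [``plateau_floor``, 1] so the deviation amplitude is
    expressed nearly uniformly inside a patch.  Pairwise Pearson correlation
    below ``max_corr`` is verified (disjoint patches are at most weakly
    anti-correlated).
    """
    if K * sparsity > 1.0:
        raise ValueError("K * sparsity must be <= 1 for disjoint patches")
    rng = np.random.default_rng(seed)
    V = mesh.n_vertices
    n_patch = int(round(sparsity * V))
    claimed = np.zeros(V, dtype=bool)
    maps: list[np.ndarray] = []
    for _ in range(K):
        x = smooth_field(mesh, rng)
        ax = np.abs(x).copy()
        ax[claimed] = -np.inf
        idx = np.argsort(ax)[::-1][:n_patch]
        m = np.zeros(V)
        thr = np.abs(x[idx]).min()
        span = np.abs(x[idx]).max() - thr
        m[idx] = np.sign(x[idx]) * (plateau_floor + (1.0 - plateau_floor)
                                    * (np.abs(x[idx]) - thr) / max(span, 1e-12))
        claimed[idx] = True
        maps.append(m)
    maps_arr = np.asarray(maps)
    for i in range(K):
        for j in range(i + 1, K):
            if abs(np.corrcoef(maps_arr[i], maps_arr[j])[0, 1]) >= max_corr:
                raise RuntimeError("factor maps unexpectedly correlated")
    return maps_arr


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------


def simulate_participants(n_per_group=(37, 39, 47), seed: int = 0) -> pd.DataFrame:
    """Participants table for (NT, ADHD, ADHD_IEO); defaults mirror the cohort split.

    Ages uniform on [5, 9.9] years, sex Bernoulli(0.7 male) for a
    predominantly-male sample, motion log-normal.
    """
    if len(n_per_group) != 3 or any(n < 2 for n in n_per_group):
        raise ValueError("n_per_group must give >= 2 participants for each of 3 groups")
    rng = np.random.default_rng(seed)
    n = int(sum(n_per_group))
    groups = np.repeat(list(GROUPS), n_per_group)
    df = pd.DataFrame({
        "id": [f"P{i:03d}" for i in range(n)],
        "group": groups,
        "age": rng.uniform(5.0, 9.9, size=n),
        "sex": rng.binomial(1, 0.7, size=n),
        "motion": rng.lognormal(mean=-2.0, sigma=0.5, size=n),
    })
    return df


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

SUBSCALES = [
    # BASC parent scales
    "bascp_hyperactivity", "bascp_aggression", "bascp_conduct",
    "bascp_attention_problems", "bascp_anxiety", "bascp_depression",
    "bascp_somatization", "bascp_withdrawal", "bascp_atypicality",
    # CBQ short form
    "cbq_activity_level", "cbq_anger", "cbq_approach", "cbq_attentional_focusing",
    "cbq_discomfort", "cbq_falling_reactivity", "cbq_fear", "cbq_high_pleasure",
    "cbq_impulsivity", "cbq_inhibitory_control", "cbq_low_pleasure",
    "cbq_perceptual_sensitivity", "cbq_sadness", "cbq_shyness", "cbq_smiling",
    # ERC (four-subscale scoring)
    "erc_negative_lability", "erc_positive_lability",
    "erc_socially_appropriate", "erc_socially_incongruent",
    # TTQ tantrum scores
    "ttq_high_anger", "ttq_low_anger", "ttq_distress",
]

_FACTOR_OF_SUBSCALE = {
    # factor 0: Externalizing
    "bascp_hyperactivity": 0, "bascp_aggression": 0, "bascp_conduct": 0,
    "bascp_attention_problems": 0, "bascp_atypicality": 0, "cbq_anger": 0,
    "cbq_attentional_focusing": 0, "cbq_inhibitory_control": 0, "cbq_low_pleasure": 0,
    # factor 1: Emotion dysregulation (TTQ + ERC + reactivity)
    "ttq_high_anger": 1, "ttq_low_anger": 1, "ttq_distress": 1,
    "erc_negative_lability": 1, "erc_positive_lability": 1,
    "erc_socially_appropriate": 1, "erc_socially_incongruent": 1,
    "cbq_falling_reactivity": 1,
    # factor 2: Internalizing
    "bascp_anxiety": 2, "bascp_depression": 2, "bascp_somatization": 2,
    "bascp_withdrawal": 2, "cbq_fear": 2, "cbq_sadness": 2, "cbq_discomfort": 2,
    "cbq_shyness": 2,
    # factor 3: Surgency/Impulsivity
    "cbq_activity_level": 3, "cbq_approach": 3, "cbq_high_pleasure": 3,
    "cbq_impulsivity": 3, "cbq_perceptual_sensitivity": 3, "cbq_smiling": 3,
}

FACTOR_NAMES = ("externalizing", "emotion_dysregulation",
                "internalizing", "surgency_impulsivity")


@dataclass
class BehaviorTruth:
    """Planted common-factor model for the questionnaire battery."""

    loadings: np.ndarray          # 31 x 4, simple structure
    phi: np.ndarray               # 4 x 4 factor correlations
    uniquenesses: np.ndarray      # 31, in [0.2, 0.5]
    group_shifts: dict[str, np.ndarray]  # group -> 4-vector of factor mean shifts
    subscales: list[str] = field(default_factory=lambda: list(SUBSCALES))


def default_behavior_truth(seed: int = 0, phi_offdiag: float = 0.3,
                           group_shifts: dict[str, np.ndarray] | None = None,
                           ) -> BehaviorTruth:
    """Simple-structure loadings with communalities in [0.5, 0.8].

    Default group shifts plant the qualitative pattern of interest:
    Externalizing highest in ADHD_IEO, Emotion dysregulation elevated only in
    ADHD_IEO, Internalizing elevated in both patient groups,
    Surgency/Impulsivity highest in ADHD.
    """
    rng = np.random.default_rng(seed)
    p, k = len(SUBSCALES), 4
    phi = np.full((k, k), phi_offdiag)
    np.fill_diagonal(phi, 1.0)
    loadings = np.zeros((p, k))
    for j, name in enumerate(SUBSCALES):
        f = _FACTOR_OF_SUBSCALE[name]
        lam = rng.uniform(0.72, 0.88)
        loadings[j, f] = lam
    # uniqueness so that each standardized variable has unit variance
    uniq = 1.0 - np.einsum("jk,kl,jl->j", loadings, phi, loadings)
    if group_shifts is None:
        group_shifts = {
            "NT": np.array([0.0, 0.0, 0.0, 0.0]),
            "ADHD": np.array([1.0, 0.0, 0.8, 0.6]),
            "ADHD_IEO": np.array([2.0, 0.8, 0.8, 0.3]),
        }
    return BehaviorTruth(loadings=loadings, phi=phi, uniquenesses=uniq,
                         group_shifts={g: np.asarray(v, dtype=float)
                                       for g, v in group_shifts.items()})


@dataclass
class BrainTruth:
    """Planted structure for the CT matrix and the rs-fMRI-like time series."""

    factor_maps: np.ndarray       # K x V, signed, in [-1, 1]
    theta: pd.DataFrame           # patients x K Dirichlet weights (non-NT ids)
    amplitude: float = 1.5        # deviation scale in units of the noise SD
    baseline: np.ndarray | None = None   # V, mm
    b_age: float = -0.02          # mm per year (developmental thinning)
    b_sex: float = 0.05           # mm
    b_motion: float = -0.15       # mm per motion unit
    noise_sd: float = 0.1         # mm, per-vertex residual SD
    # optional group-specific CT patch (e.g. a thicker DLPFC-like region)
    ct_patch: np.ndarray | None = None       # vertex indices
    ct_patch_amp: dict[str, float] | None = None  # group -> amplitude (units of noise SD)
    # functional coupling structure
    seed_region: np.ndarray | None = None    # connected vertex set
    target_patch: np.ndarray | None = None   # vertex set receiving seed coupling
    coupling: dict[str, float] = field(
        default_factory=lambda: {"NT": 0.6, "ADHD": 0.6, "ADHD_IEO": 0.2})
    leakage: float = 0.3
    ts_noise_sd: float = 1.0


def simulate_theta(participants: pd.DataFrame, K: int, seed: int,
                   concentration: float = 0.3) -> pd.DataFrame:
    """Dirichlet factor weights for every non-NT participant (rows sum to 1).

    The sub-unit concentration gives sparse mixed membership: most patients
    are dominated by one or two factors, as topic models assume.
    """
    rng = np.random.default_rng(seed)
    patients = participants.loc[participants["group"] != "NT", "id"].tolist()
    theta = rng.dirichlet(np.full(K, concentration), size=len(patients))
    return pd.DataFrame(theta, index=patients,
                        columns=[f"factor{k + 1}" for k in range(K)])


def default_brain_truth(participants: pd.DataFrame, mesh: Mesh, atlas: np.ndarray,
                        seed: int = 0, K: int = 3, amplitude: float = 1.5,
                        theta_concentration: float = 0.3,
                        ct_patch_amp: dict[str, float] | None = None) -> BrainTruth:
    """Planted maps, Dirichlet weights and FC structure on the given mesh.

    The seed region is a 30-vertex connected patch inside the penultimate
    network (a frontoparietal stand-in); the coupling target is a 40-vertex
    patch inside the last network (a default-mode stand-in).
    """
    n_networks = int(atlas.max())
    maps = make_factor_maps(mesh, K, seed=seed)
    theta = simulate_theta(participants, K, seed=seed + 1,
                           concentration=theta_concentration)
    rng = np.random.default_rng(seed + 2)
    baseline = 2.5 + 0.2 * smooth_field(mesh, rng)
    fpn = np.flatnonzero(atlas == max(n_networks - 1, 1))
    dmn = np.flatnonzero(atlas == n_networks)
    seed_region = fpn[:min(30, fpn.size)]
    target_patch = dmn[:min(40, dmn.size)]
    ct_patch = None
    if ct_patch_amp is not None:
        ct_patch = seed_region
    return BrainTruth(factor_maps=maps, theta=theta, amplitude=amplitude,
                      baseline=baseline, seed_region=seed_region,
                      target_patch=target_patch, ct_patch=ct_patch,
                      ct_patch_amp=ct_patch_amp)


# ---------------------------------------------------------------------------
# questionnaire battery
# ---------------------------------------------------------------------------


def simulate_behavior(participants: pd.DataFrame, truth: BehaviorTruth,
                      seed: int = 0, noise_scale: float = 1.0,
                      return_factors: bool = False):
    """Questionnaire matrix X = F Λᵀ + E under the planted factor model.

    Factor scores F are the per-group mean shift plus correlated unit-variance
    noise (Cholesky of Φ); unique noise has the planted uniquenesses, scaled
    by ``noise_scale`` (0 gives noiseless recovery tests).  Columns are
    standardized.
    """
    lam = truth.loadings
    p, k = lam.shape
    if not np.all((lam >= 0.5).sum(axis=1) == (lam > 0).sum(axis=1)):
        raise ValueError("each subscale must load >= 0.5 on exactly one factor")
    rng = np.random.default_rng(seed)
    n = len(participants)
    L = np.linalg.cholesky(truth.phi)
    F = rng.normal(size=(n, k)) @ L.T
    shifts = np.stack([truth.group_shifts[g] for g in participants["group"]])
    F = F + shifts
    E = rng.normal(size=(n, p)) * np.sqrt(truth.uniquenesses) * noise_scale
    X = F @ lam.T + E
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    df = pd.DataFrame(X, index=participants["id"], columns=truth.subscales)
    if return_factors:
        return df, pd.DataFrame(F, index=participants["id"],
                                columns=list(FACTOR_NAMES))
    return df


# ---------------------------------------------------------------------------
# cortical thickness
# ---------------------------------------------------------------------------


def simulate_ct(participants: pd.DataFrame, mesh: Mesh, truth: BrainTruth,
                seed: int = 0, noise_scale: float = 1.0) -> pd.DataFrame:
    """CT matrix: covariate structure everywhere, factor mixtures in patients.

    ct[d, v] = baseline(v) + b_age*age + b_sex*sex + b_motion*motion
               + [patients] amplitude * sum_k theta[d,k] * map[k,v] * noise_sd
               + [optional]  patch_amp[group] * noise_sd on the planted patch
               + N(0, (noise_scale*noise_sd)^2)

    NT participants receive no factor signal, so NT-referenced z maps have
    mean ~0 / SD ~1 under the null at every vertex.
    """
    rng = np.random.default_rng(seed)
    V = mesh.n_vertices
    if truth.factor_maps.shape[1] != V:
        raise ValueError("factor maps do not match mesh size")
    baseline = truth.baseline if truth.baseline is not None else np.full(V, 2.5)
    n = len(participants)
    ct = np.tile(baseline, (n, 1))
    ct += np.outer(truth.b_age * participants["age"].to_numpy()
                   + truth.b_sex * participants["sex"].to_numpy()
                   + truth.b_motion * participants["motion"].to_numpy(),
                   np.ones(V))
    is_patient = (participants["group"] != "NT").to_numpy()
    for i in np.flatnonzero(is_patient):
        pid = participants["id"].iloc[i]
        if pid not in truth.theta.index:
            raise ValueError(f"missing theta_true row for patient {pid}")
        w = truth.theta.loc[pid].to_numpy()
        ct[i] += truth.amplitude * truth.noise_sd * (w @ truth.factor_maps)
    if truth.ct_patch is not None and truth.ct_patch_amp is not None:
        for g, amp in truth.ct_patch_amp.items():
            rows = np.flatnonzero((participants["group"] == g).to_numpy())
            ct[np.ix_(rows, truth.ct_patch)] += amp * truth.noise_sd
    ct += rng.normal(scale=truth.noise_sd * noise_scale, size=ct.shape)
    if not np.all(np.isfinite(ct)):
        raise RuntimeError("generated CT contains non-finite values")
    return pd.DataFrame(ct, index=participants["id"],
                        columns=[f"v{v}" for v in range(V)])


# ---------------------------------------------------------------------------
# resting-state-like time series
# ---------------------------------------------------------------------------


def _confound_table(rng: np.random.Generator, T: int) -> pd.DataFrame:
    """Six slow motion traces plus WM and CSF signals (T x 8)."""
    cols = {}
    for j in range(6):
        x = np.cumsum(rng.normal(scale=0.05, size=T))
        cols[f"mot{j + 1}"] = x - x.mean()
    for name in ("wm", "csf"):
        x = rng.normal(size=T)
        cols[name] = x - x.mean()
    return pd.DataFrame(cols)


def simulate_timeseries(participants: pd.DataFrame, mesh: Mesh, atlas: np.ndarray,
                        truth: BrainTruth, seed: int = 0, T: int = 180,
                        ) -> tuple[dict[str, np.ndarray], dict[str, pd.DataFrame]]:
    """Per-participant (V, T) series plus the confound tables that drove them.

    vertex signal = own-network latent + seed latent on the seed region
                    + coupling(group) * seed latent on the target patch
                    + leakage * (motion + WM + CSF mix) + white noise.
    """
    if T < 30:
        raise ValueError("need T >= 30 time points")
    if truth.seed_region is None or truth.target_patch is None:
        raise ValueError("truth must define seed_region and target_patch")
    rng = np.random.default_rng(seed)
    V = mesh.n_vertices
    n_networks = int(atlas.max())
    ts, confounds = {}, {}
    leak_w = np.array([1.0, 0.8, 0.6, 0.4, 0.3, 0.2, 1.0, 1.0])  # mot1..6, wm, csf
    leak_w = leak_w / np.linalg.norm(leak_w)
    for _, row in participants.iterrows():
        net_latent = rng.normal(size=(n_networks, T))
        seed_latent = rng.normal(size=T)
        conf = _confound_table(rng, T)
        y = net_latent[atlas - 1]                       # V x T
        y[truth.seed_region] += seed_latent
        c = truth.coupling[row["group"]]
        y[truth.target_patch] += c * seed_latent
        leak = conf.to_numpy() @ leak_w                  # T
        y += truth.leakage * leak
        y += rng.normal(scale=truth.ts_noise_sd, size=(V, T))
        ts[row["id"]] = y
        confounds[row["id"]] = conf
    return ts, confounds


# ---------------------------------------------------------------------------
# whole-cohort bundle
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    mesh: Mesh
    atlas: np.ndarray
    participants: pd.DataFrame
    behavior: pd.DataFrame
    ct: pd.DataFrame
    behavior_truth: BehaviorTruth
    brain_truth: BrainTruth
    ts: dict[str, np.ndarray] | None = None
    confounds: dict[str, pd.DataFrame] | None = None


def simulate_cohort(seed: int = 0, n_per_group=(37, 39, 47), n_vertices: int = 700,
                    n_networks: int = 7, K: int = 3, amplitude: float = 1.5,
                    T: int = 180, include_timeseries: bool = True,
                    ct_patch_amp: dict[str, float] | None = None,
                    theta_concentration: float = 0.3) -> Cohort:
    """Generate the full five-part synthetic cohort from one seed."""
    ss = np.random.SeedSequence(seed)
    s = [int(x % (2 ** 31)) for x in ss.generate_state(6)]
    mesh, atlas = make_mesh(n_vertices, n_networks, seed=s[0])
    participants = simulate_participants(n_per_group, seed=s[1])
    btruth = default_behavior_truth(seed=s[2])
    behavior = simulate_behavior(participants, btruth, seed=s[3])
    brtruth = default_brain_truth(participants, mesh, atlas, seed=s[4], K=K,
                                  amplitude=amplitude,
                                  theta_concentration=theta_concentration,
                                  ct_patch_amp=ct_patch_amp)
    ct = simulate_ct(participants, mesh, brtruth, seed=s[5])
    ts = confounds = None
    if include_timeseries:
        ts, confounds = simulate_timeseries(participants, mesh, atlas, brtruth,
                                            seed=s[5] + 1, T=T)
    return Cohort(mesh=mesh, atlas=atlas, participants=participants,
                  behavior=behavior, ct=ct, behavior_truth=btruth,
                  brain_truth=brtruth, ts=ts, confounds=confounds)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the cohort in the delimited-text layout run_pipeline consumes."""
    import pathlib

    from .io_core import write_atlas, write_matrix, write_participants

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_participants(cohort.participants, out / "participants.csv")
    cohort.mesh.save(out / "mesh.csv")
    write_atlas(cohort.atlas, out / "atlas.csv")
    write_matrix(cohort.behavior, out / "behavior.csv",
                 "questionnaire subscales (standardized)")
    write_matrix(cohort.ct, out / "ct.csv", "cortical thickness, mm; columns v0.. are vertices")
    if cohort.ts is not None:
        (out / "ts").mkdir(exist_ok=True)
        (out / "confounds").mkdir(exist_ok=True)
        T = next(iter(cohort.ts.values())).shape[1]
        tcols = [f"t{t}" for t in range(T)]
        for pid, y in cohort.ts.items():
            write_matrix(pd.DataFrame(y.T, index=tcols,
                                      columns=[f"v{v}" for v in range(y.shape[0])]),
                         out / "ts" / f"{pid}.csv", "rows time x columns vertices")
            with open(out / "confounds" / f"{pid}.csv", "w") as fh:
                fh.write("# confounds: 6 motion + wm + csf per time point\n")
                cohort.confounds[pid].to_csv(fh, index=False)


def simulate_coupled_scores(participants: pd.DataFrame, brain_scalar: np.ndarray,
                            slope: float, seed: int = 0, residual_sd: float = 1.0,
                            b_age: float = 0.1, b_sex: float = 0.2) -> np.ndarray:
    """Behavioral score linearly coupled to a brain scalar (for recovery tests)."""
    rng = np.random.default_rng(seed)
    return (slope * np.asarray(brain_scalar)
            + b_age * participants["age"].to_numpy()
            + b_sex * participants["sex"].to_numpy()
            + rng.normal(scale=residual_sd, size=len(participants)))
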