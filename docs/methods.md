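# Methods

This note documents the models behind `dysmap`, the parameter choices that
matter, what the synthetic cohorts do and do not emulate, and the numerical
decisions a maintainer should know about. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Behavioral factor model

The questionnaire battery (31 subscales emulating BASC-P, CBQ short form,
ERC four-subscale scoring, and TTQ tantrum scores) is analyzed with
exploratory factor analysis:

- **Extraction** is minimum-residual (minres): loadings minimize the sum of
  squared *off-diagonal* residuals of `R − ΛΛᵀ`. Communalities are profiled
  out — for a candidate uniqueness vector ψ the optimal Λ comes from the
  top-k eigenpairs of `R − diag(ψ)` (negative eigenvalues clipped at 0), and
  ψ is optimized by L-BFGS-B in [0.001, 1] from a squared-multiple-correlation
  start. Reported uniquenesses are defined as `1 − communality`, so the two
  sum to one per variable by construction.
- **Rotation** is promax with power 4 (configurable): Kaiser-normalized
  varimax (GPA implementation from statsmodels), an element-wise
  `sign(B)|B|^4` target, a least-squares oblique transformation normalized
  to unit factor variances, and the implied factor correlation
  `Φ = (UᵀU)⁻¹`. Column signs are fixed so each factor's largest-|loading|
  entry is positive. Loadings ≥ 0.40 in absolute value are flagged as
  meaningful in the CLI output.
- **Factor count** guidance is the Kaiser rule (eigenvalues of R strictly
  greater than 1) with the full sorted spectrum returned for scree
  inspection; the run configuration can override the count.
- **Scores** use the regression (Thurstone) estimator `Z R⁻¹ (ΛΦ)` on
  column-standardized data. Missing cells are handled pairwise-complete in
  R; rows with any missing cell get NaN scores rather than imputed values.
  A singular R (e.g. fewer participants than variables) is repaired by
  eigenvalue clipping before scoring, with a log notice.
- **Group contrasts**: Mann–Whitney U for every factor × group-pair, exact p
  by enumeration when `n1·n2 ≤ 400` with no ties, otherwise the
  tie-corrected normal approximation. U is reported for the first sample
  (number of (x, y) pairs with x > y, halves for ties) and the rank-biserial
  effect size is `RBC = 1 − 2U/(n1·n2)`, so U = 0 gives RBC = +1. FDR is
  Benjamini–Hochberg step-up across the full 3-pair × k-factor family.

## Deviation encoding

CT matrices are converted to patient deviation documents in three steps:

1. **Confound residualization**: per-vertex OLS of CT on intercept + age +
   sex + motion, *fit on the NT group only* and applied to everyone. Fitting
   on NT keeps patient deviation signal out of the nuisance coefficients;
   the alternative (fit on all participants) is a one-line change.
2. **NT-referenced z-scoring**: `z = (ct − mean_NT)/sd_NT` per vertex, with
   the sample (n−1) SD; NT rows are excluded from the output. Residualizing
   first and z-scoring second is a deliberate ordering choice; the reverse
   order is statistically similar but mixes covariate variance into the
   reference SD.
3. **Signed count encoding**: z is clipped at `z_cap = 4` and scaled by
   `C = 10` tokens per z-unit: `n⁺ = round(C·max(z,0))`,
   `n⁻ = round(C·max(−z,0))`. Exactly one of n⁺/n⁻ is nonzero per cell (a
   z-score has one sign). Both constants are config-exposed; recovery is
   required (and verified) to be insensitive to C ∈ {5, 10, 20}. Patients
   whose document would be empty are dropped with a warning.

## Polar LDA

The generative model per token of participant d: factor `k ~ Cat(θ_d)` with
`θ_d ~ Dirichlet(α)`, vertex `v ~ Cat(β_k)`, sign `s ~ Bernoulli(γ_kv)`.

**Inference** is mean-field variational EM, chosen for a monotone, testable
bound (collapsed Gibbs is the obvious alternative and is not implemented):

- q(θ_d) is Dirichlet(φ_d); token-type responsibilities are
  `r_{dvsk} ∝ exp(E[log θ_dk])·β_kv·γ̃_skv` (softmax over k).
- β and γ are point estimates updated as smoothed ratios of expected counts:
  `β_kv ∝ E[n_kv] + η` and `γ_kv = (E[n⁺_kv] + κ)/(E[n_kv] + 2κ)`. These are
  the MAP updates under Dirichlet(η+1) and Beta(κ+1, κ+1) priors; the bound
  carries the matching `η Σ log β + κ Σ (log γ + log(1−γ))` terms, so every
  update is coordinate ascent on one objective and the ELBO trajectory is
  non-decreasing (checked to a relative 1e-6 on every fit).
- Defaults: `α = 50/K` (topic-model convention), `η = 0.01`, `κ = 1`;
  convergence at relative bound change < 1e-6 or 500 iterations. All
  config-exposed.
- **Initialization is random** (Dirichlet-ish β, γ ~ U(0.3, 0.7), jittered
  φ), so the multi-restart mechanism is meaningful: `fit` runs `n_init`
  independent restarts from child seeds and keeps the highest final bound.
  The restart child-seed sets are nested (the first seed of `n_init = n` is
  the seed of `n_init = 1`), so more restarts can never return a lower
  bound.
- `select_K` fits each K in the grid and reports the best bound plus a
  stability score: the mean matched signed-map correlation across the top-5
  restarts. Both numbers are advisory — under-fitting (merging two true
  factors) can itself be stable, so K is confirmed by the user in the
  configuration rather than auto-selected.

**Outputs**: `Pr(Vertex|Factor)` (β), polarity probabilities (γ), and
compositions `Pr(Factor|Participant)` (θ) whose rows sum to 1 (100% when
expressed as percentages). Factor maps are rendered as signed loadings
`λ = β⊙(2γ−1)` — the minimal quantity whose sign encodes thickening vs
thinning and whose magnitude encodes factor relevance; λ feeds the
conjunction map. Factor matching for recovery and stability scoring is
exhaustive over permutations (K ≤ 6), maximizing total Pearson correlation.

**Known sensitivity.** Because every deviation document carries one sign per
vertex, background noise has patient-level polarity coherence that the
token-exchangeable model cannot represent; on some cohort draws the bound
mildly rewards solutions that cluster patients by background sign patterns,
costing map recovery. Raising the polarity smoothing κ to ~50 suppresses
this failure mode (at the price of shrinking γ toward ½); κ is
config-exposed for exactly this reason. Rare cohort geometries can also
yield a blend of two planted factors that no smoothing fixes; restarts and
the stability report make such solutions visible.

## Conjunction and surface statistics

The conjunction map `c_v = Σ_k |λ_kv|` highlights vertices deviating under
any factor. The CT group GLM is OLS per vertex on intercept + group
indicators + age + sex (raw CT with covariates in the model, rather than
pre-residualized CT, to keep a single model); pairwise contrasts are tested
two-sided with the classical t distribution. The default search space is the
whole brain, matching the whole-brain vertex-wise analysis the pipeline
emulates; a config flag restricts the GLM to the conjunction-mask
(percentile 75 by default) instead. FDR selection is BH over the tested
vertices; surviving vertices split into connected components under the mesh
edge adjacency, sorted by size with ties broken by lowest minimum vertex
index, and the largest cluster is the seed ROI. Cohen's d uses ROI-mean
confound-residualized CT with the pooled-SD convention. Atlas overlap is
`100·|roi ∩ network|/|roi|` and always sums to 100.

## Seed connectivity

Nuisance regression removes intercept + 14 regressors per vertex: six
rigid-body motion parameters, their temporal derivatives (backward
differences, first row zero), WM and CSF. Seed-to-vertex connectivity is the
Pearson correlation with the unweighted ROI-mean series, Fisher-z
transformed (r clipped at ±(1−1e-7)) *before* group modeling — a field
convention choice, harmless because z is strictly monotone in r. Constant
vertex series get r = 0 and are flagged.

Cluster inference replaces parametric random-field cluster correction with a
**permutation max-cluster-size FWE test**, exact under exchangeability and
valid on an arbitrary mesh: clusters form at two-sided uncorrected
p < 0.01 (config-exposed), separately per t-sign; the null distribution of
the maximal cluster size comes from Freedman–Lane permutation (permute the
residuals of the reduced covariate-only model, add back the reduced fit,
recompute the full-model t-map); a cluster's corrected p is
`(1 + #{null ≥ size})/(1 + n_perm)`. The two groups in the contrast are
analyzed jointly with age/sex covariates; seed vertices can be excluded from
inference. Significant clusters are profiled against the network atlas by
membership percentage.

## Brain–behavior regression

Each behavioral factor score is regressed on intercept + brain scalar + age
+ sex (statsmodels OLS); the brain coefficient's estimate, SE, t, two-sided
p and a standardized slope are reported per factor. The factor score is the
outcome and the brain measure the predictor — consistent with slopes in
score-units per mm of CT. No correction across the four factors by default
(a flag adds BH), mirroring the uncorrected per-factor reporting convention
of the analysis this package reimplements.

## Synthetic cohorts: what they emulate, and what they do not

The generator is a pure function of (parameters, seed) and plants known
structure for every stage:

- **Mesh**: a torus grid (wraparound 4-neighbour lattice) stands in for a
  template cortical surface — connected, boundary-free, and cheap, with the
  same topology-level semantics for cluster extraction and atlas contiguity;
  networks are contiguous row-major chunks labeled 1..7.
- **Participants**: groups (NT, ADHD, ADHD+IEO) default to (37, 39, 47)
  (cohort split of the study being emulated, N = 123); ages uniform on
  [5, 9.9] years, sex Bernoulli(0.7 male), motion log-normal
  (median ≈ 0.14, arbitrary units).
- **Behavior**: simple-structure loadings (each subscale loads 0.72–0.88 on
  exactly one of four factors), factor correlations 0.3, uniquenesses
  implied by unit variances (≈0.2–0.5). Group shifts plant the qualitative
  pattern of interest: Externalizing NT 0 / ADHD 1.0 / IEO 2.0; Emotion
  dysregulation elevated only in IEO (0.8); Internalizing elevated in both
  patient groups (0.8); Surgency highest in ADHD (0.6).
- **CT**: baseline ≈ 2.5 mm with smooth spatial variation, age slope
  −0.02 mm/yr, sex offset 0.05 mm, motion slope −0.15 mm/unit, vertex noise
  SD 0.1 mm. Patients add `amplitude · Σ_k θ_dk · map_k(v) · σ` with
  amplitude 1.5 (in noise-SD units) and `θ_true ~ Dirichlet(0.3)` (sparse
  mixed membership: most patients dominated by one factor, as the ternary
  compositions in this literature suggest). The K = 3 planted maps are
  smoothed random fields thresholded to *spatially disjoint* signed patches
  (20% of vertices each) with magnitudes rescaled into [0.8, 1] — mirroring
  latent factors that occupy non-overlapping thinning/thickening
  territories. Disjointness and the plateau magnitudes were design choices
  made because graded, overlapping patches at this amplitude leave the
  mixture unidentifiable for *any* estimator of this model class (the
  likelihood itself prefers blends). An optional group patch (e.g. thicker
  CT in ADHD+IEO only, planted on the future seed region) supports the
  structural-recovery calibration.
- **Time series**: per-network latent signals plus a seed latent carried by
  the seed region; a 40-vertex patch of the last ("default-mode") network
  receives `coupling(group) · seed latent` with defaults NT 0.6 / ADHD 0.6 /
  IEO 0.2 (the planted IEO-specific reduction); motion/WM/CSF leakage with
  coefficient 0.3; white noise SD 1; T = 180 volumes, matching a 6-minute
  scan at TR = 2 s.

Not emulated: hemodynamics, spatial autocorrelation of noise, scanner
artifacts, realistic cortical geometry or surface smoothing, site effects,
questionnaire floor/ceiling effects. Passing recovery tests therefore show
the *estimators* work under their assumed generative conditions at realistic
sample sizes — not that real cortical data satisfy those conditions.

The structural and functional recovery calibrations run with the
factor-mixture amplitude at 0 (only the calibrated effect planted): with
mixtures simultaneously active, mixture variance inflates within-group SD at
overlapping vertices and the planted patch is only partially detected —
a power statement about overlapping effects, not a machinery defect.

## Numerical and reproducibility choices

- One global integer seed expands deterministically (SeedSequence) into
  per-stage child seeds; every stochastic stage is bit-reproducible and
  re-runnable in isolation. All derived seeds stay below 2³¹.
- Writers and readers are mutual inverses to ≤1e-12 (17-significant-digit
  text); vertex indices are 0-based everywhere and stated in file headers.
- Simulation sizes in the test suite and acceptance script (e.g. V = 700,
  n_init = 20, 20 replicates, n_perm = 200 for calibration runs) are chosen
  so the whole suite completes in minutes on one CPU while keeping
  Monte-Carlo error well inside the asserted margins; the null-calibration
  bounds use the binomial 2·SE allowance.
- Degenerate inputs fail loudly: constant questionnaire columns, zero NT
  reference SD, empty deviation documents, rank-deficient designs, empty
  ROIs, all-equal conjunction maps.
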