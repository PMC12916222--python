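# dysmap

Latent-factor mapping of behavioral and emotional dysregulation in a
three-group pediatric cohort: neurotypical children (NT), children with ADHD,
and children with ADHD plus impairing emotional outbursts (ADHD+IEO).

ADHD is heterogeneous: inattention/hyperactivity and emotion dysregulation
co-occur in varying mixtures, and group-average neuroimaging contrasts blur
that structure. `dysmap` implements a reusable, tested version of a
multimodal latent-factor pipeline for parsing it:

1. **Behavioral EFA** — exploratory factor analysis of a 31-subscale
   parent-report battery (BASC-P, CBQ, ERC, TTQ): minimum-residual (minres)
   extraction, promax rotation, eigenvalue-and-scree factor-count guidance,
   regression factor scores, and Mann–Whitney group contrasts with
   Benjamini–Hochberg FDR and rank-biserial effect sizes.
2. **Deviation encoding** — cortical thickness (CT) is residualized for age,
   sex and head motion (fit on NT only), z-scored vertex-wise against the NT
   reference, and discretized into signed token counts
   (`n± = round(C·max(±z, 0))` after clipping |z| at `z_cap`).
3. **Polar LDA** — the core model. A topic model over signed tokens: each
   patient is a document, each vertex a word, and a Bernoulli polarity
   variable lets every latent brain factor encode *where* CT deviates and in
   *which direction* (thickening vs thinning). Per token of participant *d*:

       factor  k ~ Cat(θ_d),  θ_d ~ Dirichlet(α)
       vertex  v ~ Cat(β_k)
       sign    s ~ Bernoulli(γ_kv)

   Fitting is mean-field variational EM with a monotone evidence lower
   bound, point-estimated β/γ under Dirichlet(η)/Beta(κ,κ) smoothing, many
   random restarts with bound-based selection, and a K-grid report
   (bound + cross-restart factor stability). Factor maps are rendered as
   signed loadings λ = β⊙(2γ−1); compositions Pr(Factor|Participant) sum to
   100% per participant.
4. **Conjunction + surface statistics** — vertex-wise sum of |λ| across
   factors, group GLM on CT (group + age + sex), FDR vertex selection,
   connected-cluster extraction on the mesh, Cohen's d, and overlap
   percentages against a 7-network atlas.
5. **Seed connectivity** — nuisance regression (6 motion parameters, their
   temporal derivatives, WM, CSF), seed-to-vertex Pearson/Fisher-z intrinsic
   functional connectivity, group GLM, and permutation max-cluster-size
   familywise-error correction (Freedman–Lane residual permutation).
6. **Brain–behavior regression** — each behavioral factor score on a brain
   scalar (ROI-mean CT or cluster-mean FC) plus age and sex.

No real imaging data ship with the package. A first-class synthetic-data
module generates the full five-part cohort — mesh + atlas, participants,
questionnaire battery, CT matrix, rs-fMRI-like time series — with planted
ground truth (4 behavioral factors, K signed CT factor maps mixed by
Dirichlet weights, group-modulated seed–network coupling), so every stage
has a parameter-recovery test.

## Worked example

```python
from dysmap import synthetic, deviation, efa, polar_lda

cohort = synthetic.simulate_cohort(seed=11, include_timeseries=False)

# behavioral EFA
sol = efa.fit_efa(cohort.behavior.to_numpy(), 4)
table = efa.group_compare_factors(sol.scores, cohort.participants, q=0.05)
print("eigenvalues > 1:", (sol.eigenvalues > 1).sum())
row = table[(table.group1 == "ADHD") & (table.group2 == "ADHD_IEO")].iloc[0]
print(f"factor {row.factor} ADHD vs ADHD_IEO: U={row.U:.0f}, "
      f"p_FDR={row.p_fdr:.2e}, RBC={row.rbc:.2f}")

# polar LDA on NT-referenced deviation counts
dm = deviation.deviation_map(cohort.ct.to_numpy(), cohort.participants)
counts = deviation.encode_signed_counts(
    dm.z, C=10, z_cap=4, ids=list(cohort.brain_truth.theta.index))
model = polar_lda.fit(counts, K=3, n_init=20, seed=1)
print(f"evidence lower bound: {model.bound:.1f}")
perm, corrs = polar_lda.match_factors(cohort.brain_truth.factor_maps,
                                      polar_lda.signed_loading_map(model))
print("matched map correlations:", corrs.round(3))
print("first patient composition (%):", (model.theta[0] * 100).round(1))
```

prints

```
eigenvalues > 1: 4
factor 1 ADHD vs ADHD_IEO: U=495, p_FDR=4.46e-04, RBC=0.46
evidence lower bound: -4265585.5
matched map correlations: [0.875 0.836 0.843]
first patient composition (%): [26.3 54.5 19.2]
```

Reading: the Kaiser rule recovers the four planted behavioral factors, and
the first factor (the planted "externalizing" axis) separates the two
patient groups with a moderate rank-biserial effect. The three fitted signed
CT factor maps correlate 0.84–0.88 with the planted thinning/thickening
patterns, and the first patient's CT profile decomposes into factor
contributions that sum to 100%.

The same stages are available as CLI subcommands
(`dysmap simulate | efa | lda | conjunction | fc | brainbehavior | run-all`);
`dysmap run-all cohort_dir out_dir --seed 1` chains everything and writes a
JSON stage report with the resolved per-stage seeds.

## Layout

- `src/dysmap/io_core.py` — I/O, configuration, seeds, pipeline orchestration
- `src/dysmap/synthetic.py` — synthetic cohorts with planted ground truth
- `src/dysmap/efa.py` — behavioral factor analysis and group contrasts
- `src/dysmap/deviation.py` — NT-referenced z maps and signed count encoding
- `src/dysmap/polar_lda.py` — the polar topic model (variational EM)
- `src/dysmap/surface_stats.py` — conjunction, vertex GLM, clusters, atlas overlap
- `src/dysmap/connectivity.py` — seed FC and permutation cluster FWE
- `src/dysmap/brain_behavior.py` — covariate-adjusted brain–behavior regression
- `docs/methods.md` — model details, parameter choices, limitations
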