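# Methods

This note specifies the generative model, the estimators, the default
parameters (with units and rationale), and the numerical choices made in
`epiparc`. Problem sizes quoted here are the package's own defaults, chosen
so the full experiment runs in well under a minute on one CPU while keeping
every statistical contrast identifiable.

## 1. Synthetic cortex and cohort

**Cortex graph.** Two hemispheres of `n_per_hemisphere` vertices each
(default 300, so V = 600), connected as a ring or 2-D grid (default grid,
factorized as near-square as possible). Edges never cross hemispheres;
vertices can be masked out (non-cortex). Default topology is the grid because
its degree-4 neighborhoods give the MRF smoothness term meaningful support;
a ring's degree-2 neighborhoods under-constrain boundaries.

**Group truth.** R ROIs (default 50) are assigned round-robin to K networks
(default 5): `roi_parents[r] = (r mod K) + 1`. The planted network mean
directions are the unit-normalized indicator vectors of each network's ROI
set. These are mutually orthogonal, which is the profile direction the
signal model below actually induces; requesting a minimum pairwise angle
above π/2 therefore raises an error. Group network patches are grown per
hemisphere by randomized multi-source BFS from K seeds, so every network is
spatially contiguous within each hemisphere.

**Subjects.** Subject labelings perturb the group boundary: each boundary
vertex flips to a neighboring network with probability `deviation_rate`
(default 0.1). Subject-level mean directions are drawn
μ_k^s ~ vMF(μ_k, κ=500). An optional per-network `leakage` parameter mixes a
fraction ρ = leakage·U(0.5, 1) of a random partner network's signal into a
subject's vertices, planting controllable inter-subject connectivity
variability (used to verify that the fitted ε_k track planted variability).

**Laterality planting.** Each subject is assigned a dominance group with a
target LI drawn from a truncated normal on [−1, 1] with the group's moments
(left 0.165 ± 0.106, bilateral 0.056 ± 0.074, right 0.023 ± 0.055; cohort
split 15/14/14). Greedy single-vertex transfers between the two language
networks and donor networks — boundary-adjacent vertices first, one
hemisphere per step — run until no transfer brings the realized
LI = (LH − RH)/(LH + RH) closer to the target. Stopping as soon as the LI
enters the ±0.02 tolerance band would bias achieved values ~0.017 toward the
starting LI, so planting always runs to the closest reachable value and only
flags subjects that end outside tolerance. A `frozen_ids` argument excludes
named networks from donating or receiving vertices; it implements the
specificity control in which asymmetry is planted outside the language
networks without disturbing them.

With K = 5 on V = 600 the two language networks hold ≈ 240 vertices, so one
transfer moves the LI by ≈ 2/240 ≈ 0.008 — comfortably inside the ±0.02
tolerance. K = 15 remains configurable but leaves too few language vertices
at desk scale for that granularity.

**Time series.** Network signals g_k(t) ~ N(0, 1) i.i.d. per frame. A vertex
in network k records y_v(t) = √snr·g_k(t) + N(0, 1); an ROI with parent k
records the same form. Default snr = 4 gives a vertex–ROI correlation of
snr/(snr+1) = 0.8 within a network. T = 200 frames at TR = 2 s
(≈ 6.7 min runs). Stimulation runs add `effect`·(HRF ⊛ boxcar) to vertices
of the stimulated networks, with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6, peak-normalized). Stim designs
alternate rest/stim blocks (default 8 blocks × 15 frames); analysis censors
stim blocks and the first 4 frames of each rest block to shed residual
hemodynamic response.

## 2. Connectivity profiles

For each run, each unmasked vertex's Pearson correlations to the R ROIs are
computed; the top ⌈0.10·R⌉ entries (ties broken by larger correlation, then
lower ROI index) are set to 1/√n_kept and the rest to zero, yielding unit-norm
nonnegative profiles on the sphere S^{R−1}. Zero-variance vertices produce
zero rows with a warning; a zero-variance ROI is an error (it poisons every
vertex's correlation vector).

## 3. Group vMF mixture

Density vMF(x; μ, κ) = C_R(κ)·exp(κ μᵀx) with
log C_R(κ) = (R/2−1)·log κ − (R/2)·log 2π − log I_{R/2−1}(κ), evaluated with
exponentially-scaled Bessel functions (`scipy.special.ive`) for stability up
to κ = 10⁶ and R in the hundreds. EM over K components with component-wise
κ_k: responsibilities in the log domain, spherical kmeans++-style seeding,
empty components reseeded from the worst-fit row, best of `n_init` restarts.
M-step concentrations solve A_R(κ) = r̄ (A_R = I_{R/2}/I_{R/2−1}) by Newton
iteration from the Banerjee closed-form start κ₀ = r̄(R−r̄²)/(1−r̄²); the
Newton step uses A' = 1 − A² − (R−1)A/κ. The group parcellation assigns each
vertex the argmax of its responsibilities summed over subjects and runs.

## 4. MS-HBM

Generative model, per network k:

- group mean direction μ_k (unit vector in R dimensions);
- subject means μ_k^s ~ vMF(μ_k, ε_k) — ε_k is the inter-subject
  concentration;
- session means μ_k^{s,t} ~ vMF(μ_k^s, σ_k) — intra-subject concentration;
- observed profiles x_v^{s,t} ~ vMF(μ_{l_v}^{s,t}, κ) with one shared κ;
- labels l^s follow P(l) ∝ exp(Σ_v log θ_v(l_v) + c·Σ_{(u,v)∈E} 1[l_u = l_v]),
  a spatial prior θ (V×K, Dirichlet-smoothed) plus an MRF smoothness term
  with weight c (default 1).

**Fitting (variational EM).** Maximum a posteriori point estimates of the
subject and session means degenerate: the subject means collapse onto the
group mean and ε_k diverges (the classic between-group variance collapse).
We instead use a mean-field posterior in which each subject/session mean has
a vMF factor with natural parameter a (the sum of its Markov blanket's
scaled directions); its posterior expectation is the attenuated mean
E[μ] = A_R(|a|)·a/|a|, with norm < 1. The evidence lower bound (ELBO) adds
the vMF entropies H(vMF(·, c)) = −log C_R(c) − c·A_R(c) and a Dirichlet(α=1)
term for θ. Each block update — posterior means bottom-up, μ_k as the
normalized sum of subject means, (ε, σ, κ) by the Newton solver on attenuated
mean resultant lengths, θ as (counts + α)/(S + Kα), labels by ICM — is an
exact conditional maximizer, so the ELBO is monotone (asserted in tests).
ICM sweeps visit vertices in raster order; ties break by larger θ, then lower
label index; when c = 0 the labels decouple and a vectorized argmax is used.

**Individual inference** freezes the trained parameters and alternates
closed-form session/subject posterior means with ICM sweeps until the labels
stop changing. In the collapse limit ε, σ → ∞, c = 0, uniform θ, inference
provably reduces to per-vertex nearest-mean-direction assignment of the
session-summed profile — an exact oracle used in tests.

**Network identification.** Fitted components are aligned to a reference
labeling by Hungarian matching on the vertex-overlap matrix
(`scipy.optimize.linear_sum_assignment`).

## 5. Evaluation

**Resting homogeneity**: per network, the mean correlation of member vertex
time courses with the network-mean time course; networks are combined
weighted by size. Singletons score 1 (a vertex correlates perfectly with
itself); empty networks are excluded with a warning.

**Stimulation GLM**: per vertex, OLS of the time course on
[intercept, HRF-convolved stim boxcar]; z is the t-statistic of the stim
beta. **Task inhomogeneity**: size-weighted within-network sample SD
(ddof = 1) of z; singletons score 0.

**LORO CV**: for each of a subject's n ≥ 2 runs, labels are estimated from
the other n−1 runs and the metric is scored on the held-out run.

**Six-way comparison**: three training sites share the planted ROI/mean-
direction structure but have different group topographies (siteA matches the
test cohort's). Each site contributes its group atlas and its MS-HBM,
giving 6 approaches and C(6,2) = 15 paired two-tailed t-tests per metric
(dof = n_subjects − 1), BH-FDR corrected over the 15 pairs
(`statsmodels multipletests fdr_bh`). Zero-variance difference vectors give
NaN p-values, which BH passes through unrejected. Because all sites share
the planted mean directions, the data term dominates individual inference
and different sites' MS-HBMs can converge to identical labelings; the
comparison machinery treats the resulting zero-variance pairs explicitly
rather than crashing.

**DVARS** = RMS over frames of the backward temporal difference, a data
quality index for the simulated series.

## 6. Laterality

LI is computed exactly with integer vertex counts and rational arithmetic
(`fractions.Fraction`), so planted counts reproduce bit-exactly. Subjects
with no language-network vertices have undefined LI and are dropped with a
warning. Group comparison is a one-way fixed-effects ANOVA
(`scipy.stats.f_oneway`); one-vs-rest discrimination uses ROC/AUC
(`sklearn.metrics`) on oriented scores — orientation +1 for the
left-dominant group and −1 for bilateral and right (those groups are
*less* left-lateralized). Inter-subject topographic similarity is the
per-network Dice coefficient over all subject pairs.

At the planted group moments and n = 15/14/14, the bilateral-vs-right mean
contrast is only ≈ 1.3 standard errors, so the strict three-way ordering of
sample means holds in ≈ 91% of replicates — an intrinsic property of the
effect sizes, not an estimator deficiency. Tests assert the left-vs-rest
ordering (≈ 100%) at the 95% level and the three-way ordering as a majority
property; ANOVA power at these sizes exceeds 50% comfortably.

## 7. Determinism and numerics

All randomness derives from `numpy.random.SeedSequence(root_seed)` spawned
per stage, so every artifact (including `summary.json`, with values rounded
to 10 decimals and SHA-256 content hashes) is byte-identical across reruns.
Concentrations are capped at κ = 10⁶ (beyond which `ive` underflows and the
distribution is numerically a point mass). Bessel-function work uses scaled
`ive` throughout; probabilities are handled in the log domain.

## 8. Limitations

- The signal model is stationary Gaussian with a single shared SNR; it has
  no autocorrelation, physiological noise, or motion structure, so DVARS is
  a formality here.
- Planted mean directions are orthogonal ROI indicators; real connectivity
  profiles are correlated across networks. The `leakage` knob reintroduces
  controlled cross-network correlation but is off by default.
- The cortex graphs are rings/grids, not meshes of real cortical geometry;
  Dice values at desk scale are optimistic relative to real data.
- One κ is shared across networks at the observation level (as in the
  reference MS-HBM formulation); per-network observation concentrations
  would be a small extension.
- The laterality generator plants asymmetry by boundary transfer, which
  preserves contiguity but means extreme targets (|LI| near 1) may be
  unreachable on small graphs; such subjects are flagged, never silently
  clipped.
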