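# Methods

## The model

Structural connectivity (SC) is a sparse, weighted, undirected graph over
N parcels; functional connectivity (FC) is a dense symmetric matrix of
activity correlations.  The package's premise is that FC reflects
communication over SC, operationalised by transforming SC into fully
weighted predictor matrices and fitting FC on them by ordinary least
squares, in-sample.  R² is always `1 − SS_res/SS_tot` with an intercept;
for a simple regression this equals the squared Pearson correlation.
Self-connections are excluded from every fit (a regional fit over N
parcels uses at most N−1 samples), and pairs whose predictor value is
non-finite — failed navigation routes — are dropped per fit, with the
number of samples actually used recorded.  Fits with fewer than 10 finite
pairs return NaN rather than a value.

### The predictor battery

Forty predictors in ten classes; parameters and conventions:

- **Weight-to-cost transform.** Path-based predictors convert affinities
  to costs via `C_ij = A_ij^−γ`, γ ∈ {0.125, 0.25, 0.5, 1, 2, 4}; absent
  edges get infinite cost so Dijkstra treats them uniformly.  Binary
  variants binarize at weight > 0 (the data carry no threshold).
- **Flow graphs** `A'(t) = expm(−tL) D` with the random-walk Laplacian
  `L = I − A D⁻¹` and Markov times t ∈ {1, 2.5, 5, 10}.  This choice of
  normalisation makes `expm(−tL)` column-stochastic, hence the output is
  symmetric and conserves node strengths as column marginals — both
  properties are asserted in tests.
- **Navigation** hops greedily to the neighbour nearest the target in
  Euclidean space (centroid coordinates, mm).  A route that has not
  arrived within N hops has entered a cycle and is scored +∞ in both the
  hop-count (`nav-num`) and metric-length (`nav-ms`) matrices.
- **Communicability** `expm(A)` (binary) and `expm(D^−1/2 A D^−1/2)`
  (weighted).
- **Matching index**: binary is the neighbourhood Jaccard ratio excluding
  the pair itself; weighted is the weighted Jaccard
  `Σ min(A_ik, A_jk) / Σ max(A_ik, A_jk)` over k ≠ i, j.  The min/max
  convention is chosen because it degenerates exactly to the binary
  formula on binary graphs, which the weight-sum convention does not.
- **Path transitivity**: mean matching index over all node pairs on the
  shortest path (`2/(k(k−1)) Σ_{i<j∈π} M_ij`); a direct edge gives
  `PT = M_st`.  The binary variant pairs binary matching with binary
  paths; each weighted variant pairs weighted matching with its γ-cost
  paths.
- **Shortest-path degeneracy** is resolved by a deterministic canonical
  predecessor: `pred(s,t)` is the lowest-index node j with
  `d(s,j) + C(j,t) = d(s,t)` (tolerance 1e−9 relative).  Search
  information and path transitivity both use this canonical path.
  Distances come from scipy's Dijkstra; predecessors are derived from the
  distance matrix, which makes the tie-break explicit and vectorisable.
- **Search information** `SI = −log₂ P(π)` where `P` multiplies the
  single-step transition probabilities `p_ij = A_ij / s_i` along the
  canonical shortest path; the sign is chosen so values are nonnegative
  bits.  Binary variants use binary weights for both paths and
  probabilities.
- **Mean first passage time** from the fundamental matrix
  `Z = inv(I − P + 1πᵀ)`, `MFPT_ij = (Z_jj − Z_ij)/π_j`; columns are then
  z-scored over off-diagonal entries (sample SD) to remove nodal biases.
- **Symmetrisation.** FC is symmetric, so asymmetric predictors
  (navigation, search information, z-scored MFPT) are symmetrised by the
  element-wise mean of the two directions, with ∞ dominating.  Every
  battery matrix is therefore symmetric with zero diagonal; only the two
  navigation matrices may contain non-finite entries.

### Model comparison

The greedy two-predictor search takes the best single predictor by R²,
then scans the remaining 39 for the largest two-predictor R², and reports
the improvement on the adjusted scale with p = 2 (single) and p = 3
(pair), p counting slopes plus intercept, evaluated at the n actually
used.  Unordered selected pairs are accumulated into a 40×40 count graph.
Exact R² ties resolve to the earlier battery label (deterministic,
probability ~0 in floating point).  The all-predictor model uses
minimum-norm least squares because several predictors are nearly
collinear; predictors with non-finite entries on a row's support are
dropped from that row's design.  The PCA variant standardises columns,
projects onto the top k components and refits; at full rank it equals the
all-predictor R² (asserted to 1e−10).

### Spatial permutation nulls

Spin nulls rotate the parcels' unit-sphere coordinates by a uniform
random rotation and re-assign values by one-to-one matching, so each null
map is an exact permutation of the observed values.  Matching is by exact
minimum-total-displacement assignment by default; a greedy random-order
variant is available.  System enrichment compares each system's observed
mean against its spin-null distribution — two-sided around the null
median by default, one-sided when the scientific claim is directional
(the lifespan analysis tests specifically for *negative* age
correlations concentrating in the designated systems).  All permutation
p-values carry the +1 correction; BH-FDR is fixed at q = 0.05 throughout.
The floor-effect null permutes a predictor row 100 times and flags a
region as "at floor" when its observed R² does not exceed the 95th
percentile of the permuted R²; on rows truly independent of the
predictor this flags ≈ 95% by construction (measured 0.94).

**Known limitation.** Parcel-permutation spin tests are mildly
anticonservative on smooth maps: with the p-value machinery verified
exactly calibrated against a ground-truth independent null (type-I 0.044
at nominal 0.05), the spin approximation still yields 0.07–0.11 across
100–400 parcels and correlation lengths 0.25–1.0, because a permutation
of irregular parcels cannot represent a rotation exactly and the
distortion shrinks the null variance.  The inflation vanishes as
smoothness vanishes and is far smaller than that of naive shuffles
(≈ 0.3+ on the same maps), which is the property the test suite asserts.

### Core–periphery decomposition

Coreness values are permutations of the logistic template
`C*_m = 1/(1 + exp(−(m − βN)·tan(πα/2)))`, normalised to unit sum so
`Σ_ij C_i C_j = 1`; quality is `R = Σ_{i≠j} G_ij C_i C_j`.  α (boundary
sharpness) and β (core size) are scanned over a grid of log-spaced values
on [0.01, 1] (α clipped at 0.999 to avoid the tangent singularity; the
nominal range [0, 1] cannot be log-spaced at 0).  Annealing: proposals
swap two template positions with an O(N) incremental ΔR; the initial
temperature is set to the mean |ΔR| of 100 random proposals, cooling is
geometric (×0.95) with 10N proposals per temperature, at most 150
temperatures, stopping after 30 without improvement; 25 restarts,
best kept.  On ≤ 8-node instances this attains the exhaustive optimum over
all template permutations in ≥ 95% of seeded runs.  Parameter pairs are
ranked by raw maximised R and each node's coreness is averaged over the
top 5%.  Note that raw-R ranking favours sharp small-core templates
(concentrating mass on the strongest dyad maximises the quadratic form),
so the aggregated profile is graded rather than two-valued; rank
correlations against a *binary* membership vector are therefore bounded
near 0.69 for an 8-of-40 core even under perfect separation (tie-averaged
ranks), and recovery is better summarised by the separation of group
means, which the tests assert.

### Consensus communities

Regions are compared by the Pearson correlation of their
optimal-predictor frequency vectors; modularity uses the uniform null
`B = S − γ`, with γ defaulting to the mean off-diagonal similarity.
Louvain moves are evaluated on the full signed B.  The consensus loop
runs Louvain (1000 runs by default), forms the co-assignment probability
matrix, subtracts the chance level computed analytically from each run's
community sizes (`Σ_c n_c(n_c−1)/(N(N−1))`, averaged over runs —
identical in expectation to label-permutation Monte Carlo but
deterministic), re-clusters the difference, and stops when every run
agrees (error after 50 iterations).

### Lifespan analysis

Per-subject coupling (the maximum global or regional R² over the battery)
and per-subject optimal-predictor prevalence (fraction of regions best
explained by each predictor; sums to 1) are residualised on nuisance
covariates — sex, visit time, frame count, mean framewise displacement,
total connectome weight, binary density, plus each node's binary and
weighted degree for regional analyses; covariates are z-scored for
conditioning, which leaves residuals unchanged.  Both the measure and age
are residualised, so the reported Pearson r equals the partial
correlation controlling the same covariates (asserted to 1e−10 against an
independent implementation).  Age-binned summaries use equal-count bins
with Spearman trends over bin medians as a robustness check.

The system-level claim about the regional age map is tested on the
designated declining *territory* (the union of the declining systems) with
the one-sided spin test.  Testing each declining cap separately is
geometrically underpowered at desk scale: two same-sized caps with equal
planted decline are interchangeable under rotation, so spins that map one
cap onto the other's mask reproduce the observed mean, leaving an
irreducible null exceedance of 1-2% per cap regardless of subject count —
right at the Benjamini-Hochberg rank thresholds.  The union constellation
has no such rotational near-symmetry (aligning both caps at once requires
a near-exact self-alignment), so the territory test is decisively powered.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
the biophysics:

- **Geometry**: parcels jittered on a 70 mm sphere; systems are k-means
  sectors on the unit sphere, rebalanced to within one parcel so every
  system supports system-level statistics; hemispheres by the sign of x.
- **SC**: edge presence Bernoulli with probability ∝ exp(−λd), λ = 0.02
  per mm, scaled to a target density (default 0.15); log-normal weights
  attenuated by the same decay; a minimum spanning tree over distances
  guarantees a single component.
- **FC**: row i is `a_i · z(predictor row i) + noise`, symmetrised by
  averaging and squashed into (−1, 1) by a scaled arctangent that
  preserves rank structure.  The default planted map assigns one
  predictor per system, selected by an identifiability rule: within each
  class, the member with the lowest maximum correlation to any other
  battery member (navigation excluded for its ∞ entries) — mfpt-wei,
  si-wei-4, pt-bin, euc, pl-wei-4, fg-wei-10.  Argmax recovery is only a
  well-posed benchmark for predictors without near-twins among the 39
  competitors.
- **What symmetrisation implies.** Averaging row-planted signals mixes
  each region's row with other systems' planted signals on cross-system
  pairs, so even noise-free planted R² is ~0.5–0.9, not 1.  Recovery
  claims are therefore stated for subject-averaged fits (measured ≥ 0.9
  at noise 10% of signal over 20 subjects), and passing tests demonstrate
  recovery of planted *linear mixtures*, not that real FC arises from any
  single communication process.
- **Lifespan cohorts**: ages uniform on 6–85 y; subject SC jitters a
  group template's weights (σ = 0.1 log-normal, topology fixed); the
  planted amplitude declines linearly with age by 50% in designated
  systems and 10% elsewhere (declines concentrate in specific systems,
  with weak background ageing), while noise stays at 0.5× the baseline
  amplitude, so planted regional R² spans ~0.5 (young) to ~0.2 (old
  declining systems) — the range empirical coupling values occupy.  Mean
  framewise displacement drifts with age at r ≈ 0.35 (realistic; a
  near-collinear drift would make residualisation remove the age signal
  itself), and the two declining systems share one planted predictor so
  prevalence has a single well-defined target.

## Problem sizes used by the test suite

Chosen so the full suite exercises every claim at meaningful power:
planted recovery on 100-node, 20-subject cohorts; null calibration on 500
smooth maps against 1000 spins; floor calibration on 400 independent
rows; annealing optimality on twenty 7-node instances (exhaustive
oracle); planted core on 8+32 nodes with a 21-point grid; consensus on
two- and four-block similarity matrices across 20 seeds; lifespan
detection on ten 200-subject, 48-node, 8-system cohorts (≥ 9 must
reproduce all three planted effects).  The acceptance script re-runs the
same analyses at moderately reduced sizes (12-subject recovery cohorts,
300 null maps, one lifespan cohort) to keep a full from-scratch
reproduction within a few minutes on one CPU.

## Known limitations

- In-sample OLS only; no regularisation or cross-validated prediction.
- The spin approximation's mild anticonservatism on smooth maps (above).
- Raw-R ranking in the coreness grid aggregation (above).
- The synthetic FC model is a linear mixture of predictor rows — it
  contains no haemodynamics, no indirect time-series structure, and no
  tractography biases, so conclusions about real data must come from real
  data; the synthetic cohorts validate the *machinery*.
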