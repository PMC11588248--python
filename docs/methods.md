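# Methods

## The model

Observations are curves sampled on a shared, strictly increasing time
grid t₁ < … < t_T (hours). For observation *i* belonging to cluster
*k* ∈ {1, …, K} the response satisfies a cluster-specific
function-on-function linear model

    Y_i(t) = β₀ₖ(t) + Σ_j ∫ β_jk(t, s) X_ij(s) ds + ε_i(t),

with an intercept curve β₀ₖ ∈ L²(𝒯) and one square-integrable
coefficient surface β_jk per predictor. The model assumes a common
domain for response and predictors, mean-zero functional errors, and
that the same regression map holds for every member of a cluster. The
conditional expectation operator Φ(x; β) is linear in the predictors;
all integrals are evaluated by composite trapezoid quadrature on the
observed grid (exact for piecewise-linear interpolants and agnostic to
grid spacing).

## Fitting method

Each cluster's model is fitted by penalized least squares. The
intercept is expanded in `n_basis_t` B-splines of order 4 over t; each
surface in the tensor product of that basis with `n_basis_s` B-splines
over s (open-uniform knots, equally spaced interior knots). The
objective is the quadrature-weighted squared error plus λ times a
second-difference penalty on the coefficients (over the t-index for
every term, additionally over the s-index for surfaces). Writing
z_ij = Bs' W x_ij for the predictor scores and u_i = (1, z_i1', …)',
the Gram matrix of the problem is kron(U'U, Bt' W Bt), so a fit costs
O(c³) with c = n_basis_t · (1 + p · n_basis_s) coefficients and never
materializes the stacked design (the dense design is still available
via `build_design` for verification).

λ is selected per fit by generalized cross-validation over a fixed
log-spaced grid (10⁻⁴ … 10²) unless the caller pins it; GCV uses the
effective degrees of freedom tr(A⁻¹G). A small ridge floor
(`lambda_floor`, default 10⁻⁸ relative to the Gram trace) keeps fits on
clusters smaller than the effective degrees of freedom well posed.
This fitter deliberately trades the boosting-style componentwise
selection sometimes used for such models for a deterministic,
hyperparameter-light convex fit in the same model class.

Defaults: `n_basis_t = n_basis_s = 8`, order 4. Eight cubic B-splines
resolve one to one-and-a-half oscillations per domain comfortably; a
12 h-period component over a 24 h domain (two full cycles) is at the
edge of what 8 splines represent, so analyses that rely on such
components should raise `n_basis_s` to 10–12.

## The clustering iteration

A run starts from a random partition with K non-empty clusters (one
seeded observation per cluster, remainder uniform). Each iteration fits
one model per non-empty cluster and reassigns every observation to the
model minimizing the residual-curve norm (L² by default; L¹ available
— the two behave nearly identically in practice). Ties go to the
smallest cluster index. Clusters may empty and never return, so the
number of active clusters is non-increasing; a collapse to a single
cluster returns a flagged single-cluster result rather than an error.
A run stops when two consecutive partitions coincide (converged), when
an earlier partition recurs — detected by hashing the label vector;
reported unconverged with a cycle flag — or at `max_iter` (default
300) iterations.

Consensus: L independent seeded runs (default 30; stability typically
sets in from 20–30 runs), non-convergent runs discarded, binary
co-assignment matrices summed into the consensus matrix B, and the rows
of B clustered by K-means (k-means++, 10 restarts, seed-controlled, raw
rows without scaling). If *every* run fails to converge, the final
partitions of the unconverged runs are used with a prominent warning —
discarding everything would leave no answer. Consensus K-means always
uses the requested K; empty consensus clusters are dropped from the
returned partition. All randomness derives from one master seed via
`numpy` seed sequences, so results are bitwise reproducible.

Choice of K: MSE(K) = (1/m) Σ_k Σ_{i∈C_k} r̂²_ik is computed from
models refitted once on each consensus partition (the consensus label
set has no attached models of its own; one refit is our
interpretation), and the elbow is taken as the interior K maximizing
the discrete second difference of the profile. The raw profile is
always returned so a user can overrule the elbow visually; a
constant-curvature profile yields the smallest interior K with a
warning.

## Preprocessing

Replicate-level TPM tables are reduced to median expression per gene,
time point and condition; genes must exceed the TPM threshold (default
5) at `min_timepoints` (default 20) or more time points in *every*
condition. Setting `min_timepoints = T − 5` reproduces the laxer
"above threshold except at most 5 time points" variant. Surviving
curves are centered by removing the across-gene mean curve per
condition, then smoothed by LOESS with local quadratic polynomials and
tricube weights (span: fraction of points per window, default 0.5; the
smoother is exact on globally quadratic inputs) and evaluated at the
original time points. Missing time points, irregular per-gene grids and
replicate outlier handling are out of scope.

## The synthetic-data generator

The generator emulates preprocessed circadian expression curves on the
hourly grid t_i = i, i = 1..24:

- **Predictors.** Sums of 24 h- and 12 h-period sinusoids with
  independent gamma-distributed amplitudes (mean 1, sd 0.5) and uniform
  phases, plus a 96 h-period drift (amplitude 0.5 by default),
  mean-centered across observations per time point. With the drift off,
  curves are exactly 24 h-periodic.
- **Surfaces.** Low-rank sums over three smooth modes — sin 2πτ,
  cos 2πτ, sin 4πτ on normalized time — with coefficient matrices
  C = C_base + δ·C_dev, base scale 0.08 and deviation scale 0.05 per
  entry, intercept curves built from the same modes (base scale 1.0,
  deviation 0.3). δ = 0 collapses all clusters onto one model and the
  mean pairwise surface distance grows linearly in δ. At δ = 1 the
  expected between-cluster squared prediction distance is roughly four
  times the energy of a unit-variance iid error curve (≈ 10² vs 23),
  i.e. clusters are well separated at the observation level — chosen
  once from this signal-to-noise argument.
- **Errors.** Either iid N(0, σ²) at every grid point (σ² = 1 in the
  standard scenarios) or an AR(1) process ε(t_q) = ρ ε(t_{q−1}) +
  η(t_q) with ρ = 0.5 and innovations N(0, 0.1); the recursion leaves
  the first point unspecified, and we initialize at the stationary law
  N(0, σ²/(1−ρ²)) (stationary marginal variance 0.1/0.75 ≈ 0.133).
- **Scenario presets.** `standard_scenarios()` enumerates all
  combinations K ∈ {3, 6, 9, 12} × n ∈ {500, 1000} × {iid, AR(1)}.
  Sample size is called m internally and n in the presets.
- **Matched-marginals mode.** Each cluster's surfaces act as matched
  filters at a cluster-specific frequency (24 h, 12 h, …): cluster k's
  response re-emits the amplitude and phase of the predictors'
  period-24/k component on a common 24 h output shape. Because the
  predictor components are exchangeable across frequencies, the
  cluster-conditional response marginals coincide (responses live in
  the same two-dimensional shape space with identically distributed
  coordinates), so response-only clustering is near chance while the
  input-output maps differ sharply — the setting regression-based
  clustering exists for. Supports up to 3 clusters (one per available
  frequency); the preset uses 2 so that the 12 h filter remains the
  finest structure the fit must resolve (s-basis 10).

What the generator does **not** emulate: count-level RNA-seq noise
(curves are simulated post-preprocessing, not negative-binomial
counts), replicate structure, gene-gene correlation beyond the shared
cluster map, and real circadian waveform diversity. Passing tests
therefore demonstrate correctness of the machinery and recovery under
the stated functional model, not performance on raw sequencing data.

## Numerical choices and conventions

- Pair metrics: positive class = "pair together in the first (truth)
  partition". ARI is Hubert–Arabie, computed from the pair-confusion
  counts; when the chance-correction denominator degenerates (both
  partitions trivial) it is 1 for identical partitions and 0 otherwise.
  TPR/TNR with empty denominators are reported as missing, not 0.
- FPCA baseline: curves are projected on 12 order-4 B-splines by
  quadrature-weighted least squares; the coefficient covariance is
  whitened by the basis Gram matrix so eigenfunctions are
  L²-orthonormal. The oracle scans score dimensions s = 2..12 and keeps
  the s maximizing ARI against the known truth — an upper bound for
  response-only clustering, meaningful only in simulation. The
  concatenation mode appends response and predictors along the time
  axis (blocks offset by one domain length plus one grid step); the
  concatenation scheme is a documented choice.
- Model serialization: flat (t, s, value) TSV tables, read back with
  round-trip float parsing for exact equality.

## Study-scale analysis configurations

The end-to-end test suite replicates the study designs at desk scale:
recovery at K_true = 3, m = 500 under AR(1) noise with L = 30 over 10
master seeds; the consensus-stability design at K_true = 12, n = 1000 with
20 disjoint run groups per L ∈ {5, 15, 30}; elbow
selection over K = 2..6 at m = 240; the matched-marginals comparison at
m = 150 over 10 replicates. These replications use a 6×6 tensor basis
(8×10 for matched marginals) — enough to resolve the generator's modes
while keeping a fit at a few milliseconds.

## Known limitations

- **Cold starts at large K.** The alternation amplifies weak
  composition signal in the initial random partition; with fewer than
  roughly 100–150 observations per cluster the amplification stalls in
  a mixed-partition fixed point even though the true partition is
  itself a stable fixed point. In practice K = 3–6 at n ≥ 500 recovers
  reliably, while K = 9–12 at n ≤ 1000 yields weakly informative single
  runs; consensus over many runs improves the aggregate, and its
  mean improves with L, but cannot fully overcome the cold-start limit.
  This mirrors the known sharp performance decay of the method as K
  grows.
- GCV targets prediction error, not cluster separation; per-cluster λ
  can differ across clusters of different sizes.
- The elbow criterion is a heuristic; inspect the MSE profile.
- Runtime scales as L × iterations × K × (fit cost); runs are
  independent and trivially parallelizable.
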