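# Methods

This note documents the models implemented in `hubnet`, the defaults and
why they were chosen, the numerical decisions, and the known limits of the
approximations.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Dynamics

States are `s_i ∈ {−1, +1}` (with 0 reachable only through the zero-input
case), updated by `s_i ← sign(Σ_j W_ij s_j + b_i)`.  The matrix convention
is fixed throughout the package: **row `i` lists the inputs of node `i`**,
so the update is a plain matrix-vector product and the out-degree of node
`j` is the number of nonzeros in column `j`.

Two sign conventions are supported.  The default maps a zero input sum to
0; nodes with no inputs therefore converge to 0 and effectively drop out of
the dynamics (they still count as frozen).  The `"nonneg"` variant maps
zero to +1, which turns input-less source nodes into constant drives and
mildly stabilizes the dynamics.  The default is used everywhere unless
stated.

The standard measurement protocol is: **4000 burn-in steps, then a
1000-step window**, with a fresh uniformly random 10% of the nodes updated
at each step (simultaneous reads within a step, so `update_fraction = 1`
recovers the synchronous parallel update).  A node is *frozen* when its
value is bitwise identical at every recorded step of the window — not
merely majority-stable.  A realization is a **fixed point** when the frozen
fraction is 1 and a **quasi-fixed point (QFP)** when it is ≥ 0.9; the 0.9
threshold sits where the empirical frozen-core distribution develops its
near-1 mode, separating a frozen network with a small toggling clique from
genuinely wandering dynamics.  Doubling the protocol lengths leaves the
estimates unchanged within sampling error (asserted in the test suite), so
the defaults are long enough for the sizes used here.

Initial conditions are i.i.d. uniform ±1 (configurable).  Each realization
(topology, strengths, initial state, update-subset stream) gets an
independent child seed spawned from one master seed, so every ensemble
estimate is bit-for-bit reproducible.

Only the trailing window of a trajectory is stored; the contract is that
all reported statistics depend on the recorded window alone, never on the
storage policy.  The inner loop is a numba kernel over CSR arrays, since
per-step work (≈ 0.1·N short dot products) is far too fine-grained for
vectorized numpy; update subsets come from a partial Fisher–Yates shuffle
driven by the kernel seed.

## Network ensembles

`W = T ∘ J`: the 0/1 topology `T` carries all structure, the strengths `J`
are i.i.d. standard normal on the edges.  Families:

- **SFO**: out-degrees sampled from a discretized Pareto law
  `P(k) = (γ−1) k_min^(γ−1) k^(−γ)` (inverse-CDF draws rounded
  half-away-from-zero, clamped to `[1, N−1]`; with `k_min = 0.5` draws in
  `[0.5, 1.5)` map to 1).  Each node sends its `k` edges to distinct
  uniformly chosen targets, so in-degrees come out binomial-like.  `γ > 2`
  is required for a finite-mean tail.
- **SFI**: the transpose of an SFO draw.
- **binomial**: each off-diagonal edge i.i.d. with probability `p = k/N`.
- **dense / identity / cycle**: complete graph and deterministic fixtures.

Self-loops are excluded in all generators, and target selection is without
replacement (simple graphs).  Both are modelling choices the generating
description leaves open; they match standard practice, and the hub-degree
cap `N−1` is consistent with the degree histograms the reduction is meant
to emulate.  Configuration-model wiring with prescribed joint in/out
sequences, and degree-correlated wiring, are out of scope.

What the generator does *not* emulate about real regulatory networks:
signed/structured interaction logic (strengths are symmetric Gaussians),
degree correlations, modularity, and autoregulation.  Passing tests
therefore show that the *hub mechanism* behaves as the theory predicts
under these idealized conditions, not that any particular biological
network converges.

## The lumped-hub reduction

Given a topology realization, the `m` nodes of largest out-degree (ties
broken toward the lowest index, for determinism) are merged into one
effective hub; the bulk is redrawn as an independent binomial network with
the original bulk mean degree `k_b`.  Redrawing (rather than keeping the
original bulk subgraph) is deliberate: the reduction claims that only
`(k_b, σ_h, α)` matter, so the bulk is replaced by its homogeneous
surrogate.  Edges among the merged hubs are discarded — neglecting the
hubs' internal dynamics is the approximation's stated coarseness.

Hub outgoing strengths at the three coarse-graining levels:

1. **exact pattern** — `u_i ~ N(0, c_i)` with `c_i` the number of merged
   hubs targeting bulk node `i` (summing independent unit-variance
   strengths); `u_i = 0` exactly where no hub connects.
2. **sparse Gaussian** — `u_i` nonzero with probability `α`, then
   `N(0, σ_h²)`.  `σ_h²` is extracted by second-moment matching conditional
   on being connected: the mean of `c_i` over targeted nodes.
3. **dense Gaussian** — `u_i ~ N(0, α σ_h²)` for every node; total variance
   preserved, sparseness discarded.

Hub incoming strengths `v` keep the union of the merged hubs' bulk
in-neighbors as support with fresh unit Gaussian strengths; `k_h` is the
size of that support (≈ `m` times the mean degree for sparse bulks).  For
systems built directly from `(k_b, σ_h, α)` the support is `k_h` uniformly
chosen nodes, with `k_h` defaulting to `m·k_b`.

The default lumping number is **m = 4**, configurable; the `lump`
experiment task reports per-realization `∇d` so its sensitivity to `m` can
be checked.  For `γ ≥ 2.4` ensembles `∇d` is insensitive to `m` over a
small range; for `γ = 2.2` it is not — there the largest hubs are so
dominant that the reduction depends on how many are merged, a known limit
of the approximation.  At the other end (large `γ`, hence small `α`), the
hub drive is too sparse for the mean-field analysis to apply.

**Open loop**: the hub is clamped (`h ≡ +1`, without loss of generality by
the ±symmetry) and its incoming links are disabled; the drive becomes a
constant bias `u` on the bulk.  **Closed loop**: the hub is appended as an
ordinary dynamic node with row `v` and column `u`.

## Mean-field theory

The normalized Hamming distance between two bulk trajectories evolves, for
`N → ∞`, by a deterministic one-step map; its derivative at the origin is

```
∇d = (2 k_b / π) Σ_{k'≥0} Poisson(k'; k_b)
     [ α·arctan(1/√(k'+σ_h²)) + (1−α)·arctan(1/√k') ].
```

Derivation sketch: a single flipped input changes the sign of a row whose
remaining input sum it exceeds in magnitude; for independent Gaussians
`Pr{|z₁| > η|z₂|} = (2/π)·arctan(1/η)` (isotropy of the joint density), and
rows are grouped by their number `k'` of nonzero recurrent inputs, Poisson
in the large-`N` binomial bulk.  Numerical choices:

- the `k' = 0` undriven term uses the limiting value `arctan(∞) = π/2` —
  required to reproduce the undriven chaotic regime;
- the Poisson series is truncated when the remaining tail mass drops below
  10⁻¹² (machine-accurate, replaces an arbitrary fixed cutoff);
- `σ_crit(k_b, α)` is found by doubling-bracket plus Brent root-finding and
  verified to satisfy `|∇d − 1| < 10⁻⁸`; when the `σ → ∞` limit of `∇d`
  (the undriven term weighted by `1−α`) is ≥ 1, no hub strength suppresses
  chaos and the critical strength is reported as undefined;
- all logarithms in the time-scale formulas are natural.

For `α = 1` and large `k_b` the series collapses to
`∇d ≈ 2k_b/(π√(k_b+σ_h²))`, giving the asymptotically linear critical line
`σ_crit ≈ (2/π)k_b`.

**Closed loop.**  Convergence takes `T_conv ≈ −ln(Nδ)/ln ∇d` steps for a
perturbed fraction `δ`; the hub flips with per-step probability
`(δ k_h/N)(2/π)arctan(1/√k_h)`, i.e. a typical flip time `T_flip ≈ N/(k_h δ)`
(the arctan factor is dropped in this coarse bound).  When `T_conv < T_flip`
the open-loop analysis carries over and the closed loop converges with
probability one half (hub sign consistency).  Near criticality the margin
requirement is `1 − ∇d > (k_h δ/N)·ln(δN)`; the implementation always
reports the plug-in value of this bound for the parameters at hand rather
than hard-coding any particular threshold.

A Monte-Carlo **damage-spreading oracle** estimates `∇d` directly (draw a
state, flip one bit, advance both copies one synchronous step, count
differing outputs, average); it is kept strictly independent of the
analytic series and the two are required to agree within 3 SE across both
phases in the acceptance tests (N = 5000, where finite-size corrections are
below the sampling error of ~2000 trials per point).

## Fixed points

For `N ≤ 24`, all `2^N` states are checked against
`s = sign(Ws + σ_h u)` exactly.  Two implementations must agree: a readable
blocked matrix sweep (`enumerate_fixed_points`, returns the states) and a
meet-in-the-middle counter (`count_fixed_points`: per-row half-sum tables
plus early termination at the first violated row, ~50× faster) used for the
censuses.  States with a zero row sum are never ±1 fixed points (a
measure-zero event for continuous weights).  Beyond `N = 24` enumeration is
refused; sampling-based search is out of scope.

The census ensemble is dense i.i.d. Gaussian with entry variance `1/N`, so
each node's recurrent input has unit variance and the drive scale `σ_h` is
directly comparable to it; `sign` is scale-invariant, so the undriven
census does not depend on this normalization.  The drive vector is dense
(every node driven), in contrast to the α-sparse hubs of the lumped model.

Reference laws: undriven counts pair (±s), and under the asymptotic
independence/orthogonality assumption `M/2 ~ Poisson(1/2)`; a weak
symmetry-breaking drive gives `M ~ Poisson(1)`.  Both have `E[M] = 1`.  At
`N = 16` the empirical `P(M = 0)` measurably exceeds the paired-Poisson
value — a finite-size effect (the orthogonality assumption fails at small
`N`) that the implementation is required to reproduce, not correct.

## Trajectory statistics

The participation ratio `(tr C)²/tr(C²)` of the state covariance over a
recorded segment measures the effective dimensionality of non-converging
dynamics (1 for rank-one, N for isotropic; undefined/NaN for a frozen
segment).  The autocorrelation profile is node- and time-averaged,
normalized to 1 at lag 0, with the per-node temporal mean subtracted by
default (a raw-product option exists because the centering convention is
ambiguous in parts of the literature).  Ensemble averages exclude
trajectories whose *asymptotic* autocorrelation — the mean over the last
quarter of computed lags — is ≥ 0.3, filtering frozen and near-frozen
runs.  Decay rates come from a log-linear fit over lags 0–5.  With 10% of
nodes updated per step, one "lag" of network time corresponds to ~10 update
steps; comparisons across ensembles therefore sample trajectories once per
sweep.

## Problem sizes and defaults used in the checks

The test suite regenerates everything it asserts: censuses at `N = 16`
with 10⁴ realizations per drive scale; oracle-vs-theory comparisons at
`N = 5000` over 10 parameter points; the open-loop transition at
`(k_b = 5, α = 1)`, `N = 1500`, 100 realizations per hub strength; the
factor-of-half check at `(k_b = 3, α = 0.5)` with 200 realizations per
loop mode; the SFO/SFI contrast at `N = 1000, γ = 2.2` with 200
realizations per ensemble; and the coarse-graining ladder at `N = 1500`,
`γ ∈ {2.4, 2.6}`, 200 realizations per lumping mode.  These sizes were
chosen so ensemble standard errors sit well below the effect sizes being
asserted while the full suite stays desk-scale.

## Known limitations

- The reduction fails for `γ ≈ 2.2` (sensitivity to `m`) and loses
  predictive power for large `γ` (hub too sparse for mean-field).
- Very sparse bulks fragment into disconnected components, which lowers the
  convergence probability below the mean-field prediction at small `∇d`.
- Merging `m > 1` hubs restricts the reduced system to a single open-loop
  fixed point (up to symmetry); original networks can have several,
  slightly depressing the closed-loop factor below 1/2.
- The mean-field map carries no finite-size corrections beyond the
  flip-time bound; quenched/annealed distinctions are not modelled beyond
  the single-step damage estimate.
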