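# hubnet

Boolean threshold-network dynamics organized by outgoing hubs: scale-free
ensembles, the lumped-hub reduction, a mean-field theory of the
convergence/chaos transition, and exhaustive fixed-point censuses.

## The problem

Gene regulatory networks (and many neural circuits) are directed and
heterogeneous: a typical gene is regulated by a handful of inputs, while a
few master regulators each control hundreds of targets.  The out-degree
distribution is heavy-tailed (scale-free-like), the in-degree distribution is
narrow.  How does this asymmetry shape the dynamics — in particular, the
probability that the network settles into a stable expression pattern?

`hubnet` studies this with the simplest nonlinear model: binary states
`s_i ∈ {−1, +1}` updated by a weighted majority rule

```
s(t+1) = sign(W s(t)),        W = T ∘ J,
```

where `T` is a random 0/1 topology drawn from a degree-distribution ensemble
and `J` has i.i.d. standard-Gaussian strengths on the edges.  Networks with
scale-free **out**-degrees (SFO) converge to (quasi-)fixed points far more
often than their transposes with scale-free **in**-degrees (SFI) — outgoing
hubs act as coherent drives that organize the rest of the network.

## The model at the core

**Lumped-hub reduction.**  In a finite SFO realization a handful of hubs
reach a macroscopic fraction of nodes.  The `m` largest out-hubs are merged
into one effective node and the remainder (the *bulk*) is replaced by a
homogeneous binomial network with the same mean degree `k_b`:

```
s'(t+1) = sign(W' s'(t) + u h(t))      (bulk)
h(t+1)  = sign(vᵀ s'(t))               (hub)
```

Three coarse-graining levels for the hub's outgoing strengths `u` are
provided: the *exact pattern* (`u_i ~ N(0, c_i)` with `c_i` the number of
merged hubs targeting node `i`), the *sparse Gaussian* summary
(`u_i` nonzero with probability `α`, then `N(0, σ_h²)`), and the *dense
Gaussian* one (`u_i ~ N(0, α σ_h²)` everywhere).  A realization is thus
summarized by three parameters `(k_b, σ_h, α)`.

**Mean-field damage spreading.**  Clamping the hub (`h ≡ +1`) turns it into
an external drive, and the fate of a single-bit perturbation is governed by
the derivative of the Hamming-distance map at the origin,

```
∇d = (2 k_b / π) Σ_{k'≥0} Poisson(k'; k_b) ·
      [ α·arctan(1/√(k'+σ_h²)) + (1−α)·arctan(1/√k') ],
```

with the `k' = 0` undriven term contributing π/2.  `∇d < 1` means damage
heals: the drive suppresses chaos and the system converges.  The critical
hub strength `σ_crit(k_b, α)` solves `∇d = 1`; for `α = 1` and large `k_b`
it grows linearly, `σ_crit ≈ (2/π) k_b`.  Restoring the hub as a dynamic
node (closing the loop) halves the convergence probability: the converged
bulk state is consistent with the clamped hub sign with probability 1/2,
and the hub flip time `T_flip ≈ N/(k_h δ)` exceeds the bulk convergence
time away from criticality.

**Fixed points are always there.**  Exhaustive enumeration over all `2^N`
states of small dense Gaussian networks shows `E[M] = 1` fixed points
regardless of drive; without drive the count is even (±s pairing) and
`M/2` is approximately Poisson(1/2), with measurable finite-size deviations
that the census reproduces.  What distinguishes SFO from SFI is the
*stability* of the fixed points, not their abundance.

## Worked example

```python
>>> from hubnet import mean_field as mf
>>> mf.grad_d(5.0, 0.0, 1.0)          # undriven bulk with mean degree 5
1.4492
>>> mf.sigma_crit(5.0, 1.0)           # hub strength needed to tame it
2.197
```

The undriven bulk is chaotic (`∇d = 1.45 > 1`); a fully connected hub
(`α = 1`) needs strength `σ_h > 2.20` to stabilize it.  Simulating the
reduced system well above the transition (`σ_h = 4`):

```python
>>> from hubnet import lumped_hub as lhm
>>> from hubnet.dynamics import convergence_probability
>>> params = lhm.LumpedHubParams(k_b=5.0, sigma_h=4.0, alpha=1.0, k_h=20)
>>> mf.predict(params, 1500).grad_d
0.6866
>>> convergence_probability(lhm.lumped_factory(params, 1500, loop="open"), 50, seed=7)
(1.0, 0.0)
>>> convergence_probability(lhm.lumped_factory(params, 1500, loop="closed"), 50, seed=8)
(0.44, 0.0702)
```

The open-loop system converges every time; closing the feedback loop drops
the quasi-fixed-point probability to ≈ 1/2 (here 0.44 ± 0.07 over 50
realizations), the sign-consistency factor of one half.

The same theory is available from the shell:

```
$ hubnet mft --kb 5 --sigma 2.2 --alpha 1.0 --sigma 4.0
k_b     sigma_h alpha   grad_d    sigma_crit
5       2.2     1       0.999329  2.19701
5       4       1       0.686579  2.19701
```

And the fixed-point census (here a small run; `M` is the exact count of ±1
fixed points per realization):

```python
>>> from hubnet import fixed_points as fp
>>> census = fp.fixed_point_census(16, 2000, sigma_h=0.0, seed=0)
>>> census.prob(0)
(0.6885, 0.0104)
>>> fp.mean_fixed_point_count(census)
(0.991, 0.0416)
```

Two thirds of undriven realizations have no fixed point at all, yet the
mean count is 1, as the pairing/independence theory predicts.

## Package layout

| module | contents |
| --- | --- |
| `hubnet.ensembles` | SFO/SFI/binomial/dense topologies, `W = T ∘ J` composition |
| `hubnet.dynamics` | threshold dynamics, frozen cores, convergence protocol |
| `hubnet.lumped_hub` | hub selection, three coarse-graining levels, open/closed assembly |
| `hubnet.mean_field` | `∇d`, `σ_crit`, damage-spreading oracle, time scales |
| `hubnet.fixed_points` | exhaustive enumeration, censuses, Poisson references |
| `hubnet.trajectory_stats` | participation ratio, autocorrelation, exponential fits |
| `hubnet.io` / `hubnet.experiment` / `hubnet.cli` | files, configs, `hubnet` command |

See `docs/methods.md` for the modelling choices, default parameters, and
known limits of the approximations.
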