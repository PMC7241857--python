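"""Random network ensembles for binary threshold dynamics.

A network is a weighted matrix ``W = T ∘ J`` (Hadamard product): a 0/1
topology matrix ``T`` drawn from a degree-distribution ensemble, and i.i.d.
standard-Gaussian interaction strengths ``J`` on the edges.

Orientation convention (fixed here, used everywhere in the package): row
``i`` of ``W`` lists the *inputs* of node ``i``, so the dynamics is a plain
matrix-vector product ``s(t+1) = sign(W s(t))``.  An edge ``j -> i`` (node
``j`` influences node ``i``) is the entry ``T[i, j]``; the out-degree of
node ``j`` is therefore the count of nonzeros in column ``j``.

Supported families:

``sfo``
    Scale-free *out*-degree: out-degrees are drawn from a discretized
    Pareto distribution ``P(k) ∝ k^(-gamma)``, targets chosen uniformly.
    The incoming degrees are then binomial-like.
``sfi``
    Scale-free *in*-degree: the transpose of an SFO realization.
``binomial``
    Homogeneous Erdos-Renyi-style directed graph; every off-diagonal edge
    present independently with probability ``p``.
``dense``
    Complete directed graph (no self-loops).
``identity`` / ``cycle``
    Tiny deterministic fixtures (self-loop diagonal / cyclic shift).

Self-loops are excluded in all random generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "FAMILIES",
    "EnsembleParams",
    "Topology",
    "Network",
    "sample_scale_free_degrees",
    "build_sfo_topology",
    "transpose_topology",
    "build_binomial_topology",
    "build_dense_topology",
    "build_identity_topology",
    "build_cycle_topology",
    "build_topology",
    "compose_network",
    "build_network",
]

FAMILIES = ("sfo", "sfi", "binomial", "dense", "identity", "cycle")


@dataclass(frozen=True)
class EnsembleParams:
    """Parameters naming one topology ensemble.

    Parameters
    ----------
    N : int
        Node count.
    family : str
        One of :data:`FAMILIES`.
    gamma : float, optional
        Power-law exponent of the out-degree (scale-free families).  Must
        exceed 2 so the degree distribution has a finite mean.
    k_min : float, optional
        Pareto location parameter (scale-free families); the smallest
        continuous degree before discretization.
    p : float, optional
        Edge probability (binomial family); mean degree is ``p * N``.
    seed : int
        Master RNG seed for realizations drawn from this ensemble.
    """

    N: int
    family: str
    gamma: Optional[float] = None
    k_min: Optional[float] = None
    p: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family in ("sfo", "sfi"):
            if self.gamma is None or self.gamma <= 2:
                raise ValueError(
                    "gamma > 2 required for a finite-mean degree distribution, "
                    f"got {self.gamma}"
                )
            if self.k_min is None or self.k_min <= 0:
                raise ValueError(f"k_min must be > 0, got {self.k_min}")
        if self.family == "binomial":
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ValueError(f"p must lie in [0, 1], got {self.p}")


@dataclass
class Topology:
    """Binary wiring pattern: ``adjacency[i, j] = 1`` means ``j -> i``."""

    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency, dtype=np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def out_degrees(self) -> np.ndarray:
        """Out-degree of each node (column sums)."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel().astype(np.int64)

    @property
    def in_degrees(self) -> np.ndarray:
        """In-degree of each node (row sums)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)


@dataclass
class Network:
    """Weighted network ``W = T ∘ J`` with Gaussian strengths on the edges."""

    weights: sp.csr_matrix
    topology: Optional[Topology] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def sample_scale_free_degrees(
    gamma: float, k_min: float, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` integer degrees from a discretized Pareto distribution.

    Continuous draws follow ``P(k) = (gamma-1) k_min^(gamma-1) k^(-gamma)``
    for ``k >= k_min`` (inverse-CDF sampling), are rounded half-away-from-zero
    to the nearest integer, and clamped to ``[1, n-1]``.
    """
    if gamma <= 2:
        raise ValueError(f"gamma must exceed 2 (finite-mean tail), got {gamma}")
    if k_min <= 0:
        raise ValueError(f"k_min must be positive, got {k_min}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = rng.random(n)
    # survival-function inversion: S(k) = (k_min / k)^(gamma - 1)
    x = k_min * u ** (-1.0 / (gamma - 1.0))
    k = np.floor(x + 0.5).astype(np.int64)  # round half away from zero (x > 0)
    return np.clip(k, 1, max(n - 1, 1))


def discretized_pareto_mean(gamma: float, k_min: float, k_max: int = 10**7) -> float:
    """Exact mean of the rounded-and-clamped Pareto degree law.

    Sums ``k * P(round(X) = k)`` over the integer support; used as an
    independent check of :func:`sample_scale_free_degrees`.
    """

    def survival(x: np.ndarray) -> np.ndarray:
        x = np.maximum(x, k_min)
        return (k_min / x) ** (gamma - 1.0)

    ks = np.arange(1, k_max + 1, dtype=np.float64)
    mass = survival(ks - 0.5) - survival(ks + 0.5)
    # everything beyond k_max rounds into the tail; assign it to k_max
    tail = survival(k_max + 0.5)
    return float(np.sum(ks * mass) + k_max * tail)


def build_sfo_topology(
    degrees: np.ndarray, n: int, rng: np.random.Generator | int
) -> Topology:
    """Wire a topology with the given out-degree sequence.

    Node ``j`` sends ``degrees[j]`` edges to distinct uniformly chosen
    targets other than itself; in-degrees are left unconstrained and come
    out binomial-like.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    if degrees.shape != (n,):
        raise ValueError(f"need {n} degrees, got shape {degrees.shape}")
    if degrees.min(initial=0) < 0 or degrees.max(initial=0) > n - 1:
        raise ValueError("each out-degree must lie in [0, n-1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, cols = [], []
    for j in range(n):
        d = int(degrees[j])
        if d == 0:
            continue
        targets = rng.choice(n - 1, size=d, replace=False)
        targets = targets + (targets >= j)  # skip the diagonal
        rows.append(targets)
        cols.append(np.full(d, j, dtype=np.int64))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
    adj = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return Topology(adj)


def transpose_topology(topology: Topology) -> Topology:
    """Reverse every edge; out-degrees of the result are the input's in-degrees."""
    return Topology(topology.adjacency.T.tocsr())


def build_binomial_topology(
    n: int, p: float, rng: np.random.Generator | int
) -> Topology:
    """Directed Erdos-Renyi-style graph: each off-diagonal edge i.i.d. Bernoulli(p)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, cols = [], []
    counts = rng.binomial(n - 1, p, size=n)
    for i in range(n):
        c = int(counts[i])
        if c == 0:
            continue
        sources = rng.choice(n - 1, size=c, replace=False)
        sources = sources + (sources >= i)
        rows.append(np.full(c, i, dtype=np.int64))
        cols.append(sources)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
    adj = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return Topology(adj)


def build_dense_topology(n: int) -> Topology:
    adj = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(adj, 0)
    return Topology(sp.csr_matrix(adj))


def build_identity_topology(n: int) -> Topology:
    return Topology(sp.identity(n, dtype=np.int8, format="csr"))


def build_cycle_topology(n: int) -> Topology:
    """Cyclic shift: node ``j`` feeds node ``(j + 1) mod n``."""
    rows = (np.arange(n) + 1) % n
    cols = np.arange(n)
    return Topology(
        sp.csr_matrix((np.ones(n, dtype=np.int8), (rows, cols)), shape=(n, n))
    )


def build_topology(params: EnsembleParams, rng: np.random.Generator | int) -> Topology:
    """Draw one topology realization from the ensemble."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if params.family in ("sfo", "sfi"):
        degrees = sample_scale_free_degrees(params.gamma, params.k_min, params.N, rng)
        topology = build_sfo_topology(degrees, params.N, rng)
        if params.family == "sfi":
            topology = transpose_topology(topology)
        return topology
    if params.family == "binomial":
        return build_binomial_topology(params.N, params.p, rng)
    if params.family == "dense":
        return build_dense_topology(params.N)
    if params.family == "identity":
        return build_identity_topology(params.N)
    if params.family == "cycle":
        return build_cycle_topology(params.N)
    raise ValueError(f"unknown family {params.family!r}")


def compose_network(
    topology: Topology, rng: np.random.Generator | int, metadata: dict | None = None
) -> Network:
    """Attach i.i.d. standard-Gaussian strengths to the edges of ``topology``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    adj = topology.adjacency.tocsr()
    weights = sp.csr_matrix(
        (rng.standard_normal(adj.nnz), adj.indices.copy(), adj.indptr.copy()),
        shape=adj.shape,
    )
    return Network(weights=weights, topology=topology, metadata=dict(metadata or {}))


def build_network(params: EnsembleParams, rng: np.random.Generator | int) -> Network:
    """Draw one full realization ``W = T ∘ J`` from the ensemble."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    topology = build_topology(params, rng)
    meta = {"family": params.family, "N": params.N}
    if params.gamma is not None:
        meta["gamma"] = params.gamma
    if params.k_min is not None:
        meta["k_min"] = params.k_min
    if params.p is not None:
        meta["p"] = params.p
    return compose_network(topology, rng, metadata=meta)
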