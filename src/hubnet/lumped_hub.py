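"""Lumped-hub reduction of heterogeneous networks.

A finite scale-free-out network is dominated by a handful of outgoing hubs
that each reach a macroscopic fraction of the nodes.  The reduction replaces
the ``m`` largest-out-degree nodes by a single effective hub, and the rest
of the network (the *bulk*) by a homogeneous binomial network with the same
mean degree ``k_b``.  The reduced system is

    s'(t+1) = sign(W' s'(t) + u h(t))        (bulk)
    h(t+1)  = sign(v^T s'(t))                (hub)

with ``u`` the hub's outgoing strengths and ``v`` its incoming ones.  Three
coarse-graining levels for ``u`` are provided:

``exact_pattern``
    ``u_i ~ N(0, c_i)`` where ``c_i`` counts how many of the ``m`` lumped
    hubs target bulk node ``i`` (summing independent unit-variance strengths
    preserves the exact support and per-node variance).
``sparse_gaussian``
    Only the statistics survive: ``u_i`` is nonzero with probability
    ``alpha`` (the hub sparseness) and then ``N(0, sigma_h^2)``.
``dense_gaussian``
    Sparseness is discarded: every ``u_i ~ N(0, alpha * sigma_h^2)``
    (same total variance, no zero entries).

In the *open-loop* setting the hub is clamped (``h ≡ +1``) and acts as an
external drive; in the *closed-loop* setting it is a dynamic node wired by
``u`` and ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .ensembles import Topology, build_binomial_topology, compose_network

__all__ = [
    "LUMPING_MODES",
    "DEFAULT_M",
    "LumpedHubParams",
    "LumpedHubNetwork",
    "AssembledSystem",
    "select_top_hubs",
    "extract_lumped_params",
    "lump_exact_pattern",
    "build_sparse_gaussian",
    "build_dense_gaussian",
    "assemble_system",
    "lumped_factory",
]

LUMPING_MODES = ("exact_pattern", "sparse_gaussian", "dense_gaussian")

#: Default number of leading hubs merged into the effective node.
DEFAULT_M = 4


@dataclass(frozen=True)
class LumpedHubParams:
    """Three-parameter summary of a lumped-hub system (plus lumping bookkeeping).

    Parameters
    ----------
    k_b : float
        Mean out-degree of the bulk.
    sigma_h : float
        Hub connection-strength scale: the root-mean-square hub strength
        conditional on a node being targeted at all.
    alpha : float
        Hub sparseness — fraction of bulk nodes receiving hub input.
    m : int
        Number of original hubs merged into the effective node.
    k_h : float
        Hub in-degree (number of bulk nodes feeding the effective hub,
        roughly ``m`` times the mean degree).
    """

    k_b: float
    sigma_h: float
    alpha: float
    m: int = DEFAULT_M
    k_h: float = 0.0

    def __post_init__(self) -> None:
        if self.k_b < 0:
            raise ValueError(f"k_b must be >= 0, got {self.k_b}")
        if self.sigma_h < 0:
            raise ValueError(f"sigma_h must be >= 0, got {self.sigma_h}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")


@dataclass
class LumpedHubNetwork:
    """Reduced system: homogeneous bulk plus one effective hub."""

    bulk_weights: sp.csr_matrix
    hub_out: np.ndarray  # u
    hub_in: np.ndarray  # v
    hub_state: int = 1
    mode: str = "sparse_gaussian"
    params: Optional[LumpedHubParams] = None

    @property
    def n_bulk(self) -> int:
        return self.bulk_weights.shape[0]


@dataclass
class AssembledSystem:
    """Weights (+ optional constant drive) ready for the dynamics module."""

    weights: sp.csr_matrix
    bias: Optional[np.ndarray]
    loop: str

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def select_top_hubs(topology: Topology, m: int) -> np.ndarray:
    """Indices of the ``m`` largest-out-degree nodes (ties -> lowest index)."""
    n = topology.n
    if not (1 <= m <= n):
        raise ValueError(f"m must lie in [1, {n}], got {m}")
    out = topology.out_degrees
    # stable sort on -degree keeps the lowest index first among ties
    order = np.argsort(-out, kind="stable")
    return order[:m]


def _lump_geometry(topology: Topology, m: int):
    """Shared bookkeeping: hub set, bulk set, target counts, bulk degree."""
    hubs = select_top_hubs(topology, m)
    n = topology.n
    bulk = np.setdiff1d(np.arange(n), hubs, assume_unique=True)
    adj = topology.adjacency.tocsc()
    # counts[i]: how many of the m hubs point at bulk node i (column j of the
    # adjacency holds the targets of node j)
    counts = np.zeros(n, dtype=np.int64)
    for h in hubs:
        col = adj.indices[adj.indptr[h] : adj.indptr[h + 1]]
        counts[col] += 1
    counts = counts[bulk]
    bulk_adj = topology.adjacency[bulk][:, bulk]
    n_bulk = bulk.size
    k_b = bulk_adj.nnz / n_bulk if n_bulk else 0.0
    # bulk nodes feeding at least one of the m hubs (hub in-neighbors)
    hub_rows = topology.adjacency[hubs][:, bulk]
    in_support = np.unique(hub_rows.tocoo().col)
    return hubs, bulk, counts, k_b, in_support


def extract_lumped_params(topology: Topology, m: int = DEFAULT_M) -> LumpedHubParams:
    """Moment-matched (k_b, sigma_h, alpha, k_h) of one topology realization.

    ``sigma_h^2`` is the mean hub-target count conditional on being targeted,
    which matches the second moment of the exact-pattern strengths to the
    sparse-Gaussian law.
    """
    _, bulk, counts, k_b, in_support = _lump_geometry(topology, m)
    targeted = counts > 0
    alpha = float(targeted.mean()) if bulk.size else 0.0
    sigma_h = float(np.sqrt(counts[targeted].mean())) if targeted.any() else 0.0
    return LumpedHubParams(
        k_b=float(k_b), sigma_h=sigma_h, alpha=alpha, m=m, k_h=float(in_support.size)
    )


def lump_exact_pattern(
    topology: Topology, m: int = DEFAULT_M, rng: np.random.Generator | int = 0
) -> LumpedHubNetwork:
    """Exact-pattern reduction of one topology realization.

    The hub strength to bulk node ``i`` is drawn ``N(0, c_i)`` with ``c_i``
    its hub-target count (zero where no lumped hub connects); the bulk is an
    independent binomial redraw with the original bulk mean degree; the hub's
    incoming links keep the union of the original hubs' bulk in-neighbors
    with fresh unit-Gaussian strengths.  Hub-to-hub edges are discarded.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    _, bulk, counts, k_b, in_support = _lump_geometry(topology, m)
    n_bulk = bulk.size
    u = rng.standard_normal(n_bulk) * np.sqrt(counts)
    p = min(k_b / (n_bulk - 1), 1.0) if n_bulk > 1 else 0.0
    bulk_net = compose_network(build_binomial_topology(n_bulk, p, rng), rng)
    v = np.zeros(n_bulk)
    v[in_support] = rng.standard_normal(in_support.size)
    targeted = counts > 0
    params = LumpedHubParams(
        k_b=float(k_b),
        sigma_h=float(np.sqrt(counts[targeted].mean())) if targeted.any() else 0.0,
        alpha=float(targeted.mean()) if n_bulk else 0.0,
        m=m,
        k_h=float(in_support.size),
    )
    return LumpedHubNetwork(
        bulk_weights=bulk_net.weights,
        hub_out=u,
        hub_in=v,
        mode="exact_pattern",
        params=params,
    )


def _hub_in_vector(params: LumpedHubParams, n_bulk: int, rng: np.random.Generator):
    k_h = int(round(params.k_h)) if params.k_h > 0 else int(round(params.m * params.k_b))
    k_h = max(min(k_h, n_bulk), 0)
    v = np.zeros(n_bulk)
    if k_h:
        support = rng.choice(n_bulk, size=k_h, replace=False)
        v[support] = rng.standard_normal(k_h)
    return v


def build_sparse_gaussian(
    params: LumpedHubParams, n_bulk: int, rng: np.random.Generator | int = 0
) -> LumpedHubNetwork:
    """Sparse-Gaussian system: ``u_i ~ alpha-Bernoulli × N(0, sigma_h^2)``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = min(params.k_b / (n_bulk - 1), 1.0) if n_bulk > 1 else 0.0
    bulk_net = compose_network(build_binomial_topology(n_bulk, p, rng), rng)
    mask = rng.random(n_bulk) < params.alpha
    u = np.where(mask, rng.standard_normal(n_bulk) * params.sigma_h, 0.0)
    v = _hub_in_vector(params, n_bulk, rng)
    return LumpedHubNetwork(
        bulk_weights=bulk_net.weights, hub_out=u, hub_in=v,
        mode="sparse_gaussian", params=params,
    )


def build_dense_gaussian(
    params: LumpedHubParams, n_bulk: int, rng: np.random.Generator | int = 0
) -> LumpedHubNetwork:
    """Dense-Gaussian system: every ``u_i ~ N(0, alpha * sigma_h^2)``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = min(params.k_b / (n_bulk - 1), 1.0) if n_bulk > 1 else 0.0
    bulk_net = compose_network(build_binomial_topology(n_bulk, p, rng), rng)
    u = rng.standard_normal(n_bulk) * (np.sqrt(params.alpha) * params.sigma_h)
    v = _hub_in_vector(params, n_bulk, rng)
    return LumpedHubNetwork(
        bulk_weights=bulk_net.weights, hub_out=u, hub_in=v,
        mode="dense_gaussian", params=params,
    )


def assemble_system(lh: LumpedHubNetwork, loop: str = "open") -> AssembledSystem:
    """Turn a lumped-hub network into a plain weight matrix for simulation.

    ``open``: the hub is clamped at its current state, its incoming links are
    disabled, and its drive ``u * h`` becomes a constant bias on the bulk.
    ``closed``: the hub is appended as node ``n_bulk`` with incoming row
    ``v`` and outgoing column ``u``.
    """
    if loop == "open":
        bias = lh.hub_out * float(lh.hub_state)
        return AssembledSystem(weights=lh.bulk_weights.tocsr(), bias=bias, loop="open")
    if loop == "closed":
        n = lh.n_bulk
        u_col = sp.csr_matrix(lh.hub_out.reshape(n, 1))
        v_row = sp.csr_matrix(lh.hub_in.reshape(1, n))
        W = sp.bmat([[lh.bulk_weights, u_col], [v_row, None]], format="csr")
        return AssembledSystem(weights=W, bias=None, loop="closed")
    raise ValueError(f"loop must be 'open' or 'closed', got {loop!r}")


def lumped_factory(params: LumpedHubParams, n_bulk: int, mode: str = "sparse_gaussian",
                   loop: str = "open"):
    """Realization factory for ``dynamics.convergence_probability``.

    Returns a callable ``factory(rng) -> (weights, bias)`` drawing an
    independent lumped-hub system per call.
    """
    if mode not in ("sparse_gaussian", "dense_gaussian"):
        raise ValueError(
            "lumped_factory builds statistics-level systems; for exact_pattern "
            "lump a concrete topology with lump_exact_pattern"
        )
    builder = build_sparse_gaussian if mode == "sparse_gaussian" else build_dense_gaussian

    def factory(rng: np.random.Generator):
        lh = builder(params, n_bulk, rng)
        system = assemble_system(lh, loop=loop)
        return system.weights, system.bias

    return factory
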