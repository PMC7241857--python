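"""Tiny hand-checkable networks used in examples and tests."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .ensembles import (
    Network,
    Topology,
    build_cycle_topology,
    build_identity_topology,
)

__all__ = [
    "identity_network",
    "cycle_network",
    "flipflop_network",
]


def identity_network(n: int, weight: float = 1.0) -> Network:
    """Pure self-coupling: every ±1 state is fixed when the weight is positive."""
    W = sp.identity(n, format="csr") * weight
    return Network(weights=W.tocsr(), topology=build_identity_topology(n))


def cycle_network(n: int, signs=None) -> Network:
    """Cyclic shift ``s_i(t+1) = w_i s_{i-1}(t)`` with unit-magnitude weights.

    With all positive weights the two uniform states are the only fixed
    points; negating an odd number of weights leaves none.
    """
    topology = build_cycle_topology(n)
    signs = np.ones(n) if signs is None else np.asarray(signs, dtype=np.float64)
    if signs.shape != (n,):
        raise ValueError(f"signs must have shape ({n},)")
    rows = (np.arange(n) + 1) % n
    cols = np.arange(n)
    W = sp.csr_matrix((signs, (rows, cols)), shape=(n, n))
    return Network(weights=W, topology=topology)


def flipflop_network() -> Network:
    """Two-node cross coupling ``W = [[0, 1], [-1, 0]]``.

    Under synchronous update the dynamics is a quarter rotation of the ±1
    square: (+,+) -> (+,-) -> (-,-) -> (-,+) -> (+,+), a period-4 orbit with
    no frozen node.
    """
    W = sp.csr_matrix(np.array([[0.0, 1.0], [-1.0, 0.0]]))
    topo = Topology(sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=np.int8)))
    return Network(weights=W, topology=topo)
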