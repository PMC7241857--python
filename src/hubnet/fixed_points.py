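"""Exhaustive fixed-point enumeration and ensemble censuses.

For small networks every ±1 state can be checked against the fixed-point
condition ``s = sign(W s + sigma_h u)`` exactly.  Undriven networks have a
±s pairing symmetry (sign is odd), so fixed points come in pairs and the
count ``M`` is always even; adding a dense Gaussian drive ``u`` breaks the
symmetry.  Under the mean-field assumption that distinct fixed points are
independent, ``M/2`` is asymptotically Poisson(1/2) without drive and ``M``
is Poisson(1) with a weak drive; the expected count is exactly one in both
cases.  Finite networks deviate measurably from the Poisson reference — the
census reports the empirical law so such deviations are visible, not hidden.

States whose input sum is exactly zero in some row (sign -> 0) are never ±1
fixed points; this is a measure-zero event for continuous weights.

The census counter sweeps all ``2^N`` states with meet-in-the-middle row
tables (each row's input sum is a low-half plus a high-half table lookup)
and stops at the first violated row; the plain blocked enumeration is kept
as the readable reference path and both must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.stats import poisson

__all__ = [
    "MAX_EXHAUSTIVE_N",
    "FixedPointCensus",
    "PoissonReference",
    "enumerate_fixed_points",
    "count_fixed_points",
    "fixed_point_census",
    "poisson_reference",
    "mean_fixed_point_count",
]

#: Exhaustive enumeration is refused beyond this size (2^N blow-up); larger
#: networks need sampling-based search, which is out of scope here.
MAX_EXHAUSTIVE_N = 24

_BLOCK = 1 << 16  # states per enumeration block (memory bound)


@dataclass
class FixedPointCensus:
    """Per-realization fixed-point counts of a random ensemble."""

    M_counts: np.ndarray
    sigma_h: float
    N: int

    @property
    def n_realizations(self) -> int:
        return int(self.M_counts.size)

    def distribution(self, m_max: Optional[int] = None) -> np.ndarray:
        """Empirical probabilities ``P(M = m)`` for ``m = 0..m_max``."""
        top = int(self.M_counts.max(initial=0))
        m_max = top if m_max is None else m_max
        probs = np.bincount(self.M_counts, minlength=m_max + 1)[: m_max + 1]
        return probs / self.n_realizations

    def prob(self, m: int):
        """``P(M = m)`` with its binomial standard error."""
        p = float(np.mean(self.M_counts == m))
        se = float(np.sqrt(p * (1.0 - p) / self.n_realizations))
        return p, se


@dataclass(frozen=True)
class PoissonReference:
    """Poisson reference law for the fixed-point count ``M``.

    ``paired=True`` models ``M/2 ~ Poisson(lam)`` (all odd counts
    impossible); ``paired=False`` models ``M ~ Poisson(lam)`` directly.
    """

    lam: float
    paired: bool

    def pmf(self, m_max: int) -> np.ndarray:
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        m = np.arange(m_max + 1)
        if self.paired:
            out = np.zeros(m_max + 1)
            even = m[m % 2 == 0]
            out[even] = poisson.pmf(even // 2, self.lam)
            return out
        return poisson.pmf(m, self.lam)

    @property
    def mean(self) -> float:
        return (2.0 if self.paired else 1.0) * self.lam


def _state_block(n: int, lo: int, hi: int) -> np.ndarray:
    """±1 state matrix of shape (n, hi - lo) for state codes lo..hi-1."""
    codes = np.arange(lo, hi, dtype=np.int64)
    bits = (codes[None, :] >> np.arange(n)[:, None]) & 1
    return (2.0 * bits - 1.0).astype(np.float64)


def _check_size(n: int) -> None:
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(
            f"exhaustive enumeration refused for N = {n} > {MAX_EXHAUSTIVE_N}; "
            "use sampling-based fixed-point search instead"
        )


def enumerate_fixed_points(
    W: np.ndarray,
    u: Optional[np.ndarray] = None,
    sigma_h: float = 0.0,
    block: int = _BLOCK,
) -> np.ndarray:
    """All ±1 fixed points of ``s = sign(W s + sigma_h u)``, exactly.

    Returns an array of shape ``(M, N)`` with one fixed point per row.  The
    enumeration sweeps all ``2^N`` states in memory-bounded blocks; the
    result is independent of the block size.
    """
    W = np.asarray(W, dtype=np.float64)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError(f"W must be square, got {W.shape}")
    _check_size(n)
    drive = None
    if u is not None and sigma_h != 0.0:
        drive = sigma_h * np.asarray(u, dtype=np.float64).reshape(n, 1)
    found = []
    total = 1 << n
    for lo in range(0, total, block):
        S = _state_block(n, lo, min(lo + block, total))
        H = W @ S
        if drive is not None:
            H = H + drive
        # sign match on every row <=> H * S > 0 everywhere (S is ±1; a zero
        # input sum fails, as sign(0) = 0 can never equal ±1)
        ok = np.all(H * S > 0, axis=0)
        if ok.any():
            found.append(S[:, ok].T.astype(np.int8))
    if not found:
        return np.empty((0, n), dtype=np.int8)
    return np.vstack(found)


@njit(cache=True)
def _count_fixed_points_kernel(W, drive):
    """Count ±1 solutions of ``s = sign(W s + drive)`` over all 2^n states.

    Each row's input sum splits into a low-bits and a high-bits partial sum,
    tabulated once; a state is rejected at the first row whose sign
    disagrees (on average only ~2 rows are ever examined per state).
    """
    n = W.shape[0]
    nl = n // 2
    nh = n - nl
    size_l = 1 << nl
    size_h = 1 << nh
    A = np.empty((n, size_l))  # low-half partial sums, drive folded in
    B = np.empty((n, size_h))  # high-half partial sums
    for i in range(n):
        for a in range(size_l):
            acc = drive[i]
            for j in range(nl):
                s = 1.0 if (a >> j) & 1 else -1.0
                acc += W[i, j] * s
            A[i, a] = acc
        for b in range(size_h):
            acc = 0.0
            for j in range(nh):
                s = 1.0 if (b >> j) & 1 else -1.0
                acc += W[i, nl + j] * s
            B[i, b] = acc
    count = 0
    for b in range(size_h):
        for a in range(size_l):
            ok = True
            for i in range(n):
                if i < nl:
                    s = 1.0 if (a >> i) & 1 else -1.0
                else:
                    s = 1.0 if (b >> (i - nl)) & 1 else -1.0
                if s * (A[i, a] + B[i, b]) <= 0.0:
                    ok = False
                    break
            if ok:
                count += 1
    return count


def count_fixed_points(
    W: np.ndarray, u: Optional[np.ndarray] = None, sigma_h: float = 0.0
) -> int:
    """Exact number of ±1 fixed points of one dense network."""
    W = np.asarray(W, dtype=np.float64)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError(f"W must be square, got {W.shape}")
    _check_size(n)
    drive = np.zeros(n)
    if u is not None and sigma_h != 0.0:
        drive = sigma_h * np.asarray(u, dtype=np.float64).ravel()
    return int(_count_fixed_points_kernel(W, drive))


def fixed_point_census(
    N: int,
    n_realizations: int,
    sigma_h: float = 0.0,
    seed: int = 0,
) -> FixedPointCensus:
    """Census of fixed-point counts over dense i.i.d. Gaussian networks.

    Each realization draws ``W`` (N×N, i.i.d. Gaussian with variance 1/N,
    so every node's recurrent input has unit variance) and a dense drive
    vector ``u`` (i.i.d. standard normal), and counts the ±1 solutions of
    ``s = sign(W s + sigma_h u)`` by exhaustive enumeration.  The 1/N
    normalization makes ``sigma_h`` directly comparable to the recurrent
    input scale; since ``sign`` is scale-invariant, the undriven census is
    identical in law to one with unnormalized standard-normal entries.
    """
    _check_size(N)
    if n_realizations < 1:
        raise ValueError(f"n_realizations must be >= 1, got {n_realizations}")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_realizations, dtype=np.int64)
    zero = np.zeros(N)
    scale = 1.0 / np.sqrt(N)
    for r in range(n_realizations):
        W = scale * rng.standard_normal((N, N))
        if sigma_h != 0.0:
            drive = sigma_h * rng.standard_normal(N)
        else:
            drive = zero
        counts[r] = _count_fixed_points_kernel(W, drive)
    return FixedPointCensus(M_counts=counts, sigma_h=sigma_h, N=N)


def poisson_reference(lam: float, paired: bool) -> PoissonReference:
    """Poisson reference law: ``M/2 ~ Poisson(lam)`` if paired, else ``M``."""
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    return PoissonReference(lam=lam, paired=paired)


def mean_fixed_point_count(census: FixedPointCensus):
    """Sample mean of ``M`` with its standard error."""
    counts = census.M_counts
    if counts.size == 0:
        raise ValueError("census is empty")
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(counts.size)) if counts.size > 1 else np.inf
    return mean, se
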