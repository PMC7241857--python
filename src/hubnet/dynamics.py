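"""Binary threshold dynamics, frozen cores, and convergence statistics.

The model is ``s(t+1) = sign(W s(t) + b)`` applied to a random subset of
nodes per step (asynchronous parallel update); ``b`` is an optional constant
drive (used for the clamped hub in the open-loop setting).  ``sign`` has two
variants: the default maps a zero input sum to 0, which effectively prunes
nodes with no inputs; the ``"nonneg"`` variant maps it to +1, turning such
source nodes into constant drives.

A trajectory *freezes* a node when its value is bitwise identical at every
recorded step of a measurement window; the frozen-core fraction over a
window after a burn-in period classifies realizations as fixed points
(fraction 1), quasi-fixed points (fraction >= 0.9 by default), or neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from ._kernels import simulate_threshold

__all__ = [
    "SIGN_VARIANTS",
    "StateTrajectory",
    "ConvergenceSummary",
    "DEFAULT_PROTOCOL",
    "step",
    "run_dynamics",
    "frozen_core_fraction",
    "classify_convergence",
    "simulate_convergence",
    "convergence_probability",
    "estimate_convergence_probability",
]

SIGN_VARIANTS = ("zero", "nonneg")

#: Measurement protocol used throughout the package: 4000 burn-in steps,
#: then a 1000-step window over which frozen nodes are counted, with 10%
#: of the nodes updated per step.
DEFAULT_PROTOCOL = {"burn_in": 4000, "window": 1000, "update_fraction": 0.1}


def _zero_value(sign_variant: str) -> int:
    if sign_variant not in SIGN_VARIANTS:
        raise ValueError(f"sign_variant must be one of {SIGN_VARIANTS}, got {sign_variant!r}")
    return 0 if sign_variant == "zero" else 1


@dataclass
class StateTrajectory:
    """Recorded tail of a simulated trajectory.

    ``states[r]`` is the full state at time ``record_start + r``; entries
    lie in {-1, 0, +1} (0 only through the zero-input case of the default
    sign variant).
    """

    states: np.ndarray  # (n_recorded, N) int8
    update_fraction: float
    steps: int
    record_start: int = 0

    @property
    def n(self) -> int:
        return self.states.shape[1]

    @property
    def n_recorded(self) -> int:
        return self.states.shape[0]


@dataclass
class ConvergenceSummary:
    frozen_fraction: float
    classification: str  # fixed_point | qfp | none
    qfp_threshold: float = 0.9
    burn_in_steps: int = DEFAULT_PROTOCOL["burn_in"]
    window_steps: int = DEFAULT_PROTOCOL["window"]


def _as_csr(weights) -> sp.csr_matrix:
    if sp.issparse(weights):
        return weights.tocsr().astype(np.float64)
    return sp.csr_matrix(np.asarray(weights, dtype=np.float64))


def step(
    weights,
    s: np.ndarray,
    update_set: Optional[Sequence[int]] = None,
    sign_variant: str = "zero",
    bias: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One update of the threshold dynamics (pure-numpy reference path).

    Nodes in ``update_set`` (default: all, i.e. synchronous) are replaced by
    ``sign(W s + b)`` computed from the *current* state; others keep their
    value.
    """
    W = _as_csr(weights)
    s = np.asarray(s)
    if s.shape[0] != W.shape[0]:
        raise ValueError(f"state has {s.shape[0]} entries for a {W.shape[0]}-node network")
    if not np.isin(s, (-1, 0, 1)).all():
        raise ValueError("state entries must lie in {-1, 0, +1}")
    h = W @ s.astype(np.float64)
    if bias is not None:
        h = h + np.asarray(bias, dtype=np.float64)
    if sign_variant == "zero":
        new = np.sign(h)
    elif sign_variant == "nonneg":
        new = np.where(h >= 0, 1.0, -1.0)
    else:
        raise ValueError(f"sign_variant must be one of {SIGN_VARIANTS}, got {sign_variant!r}")
    new = new.astype(s.dtype)
    if update_set is None:
        return new
    out = s.copy()
    idx = np.asarray(update_set, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= W.shape[0]):
        raise ValueError("update_set contains out-of-range node indices")
    out[idx] = new[idx]
    return out


def run_dynamics(
    weights,
    s0: np.ndarray,
    total_steps: int,
    update_fraction: float = DEFAULT_PROTOCOL["update_fraction"],
    seed: int = 0,
    sign_variant: str = "zero",
    bias: Optional[np.ndarray] = None,
    record_window: Optional[int] = None,
) -> StateTrajectory:
    """Simulate the dynamics, recording the trailing ``record_window`` steps.

    A fresh uniform subset of ``round(update_fraction * N)`` distinct nodes
    is updated at each step; ``update_fraction = 1`` reproduces the
    synchronous parallel update.  The subset stream is reproducible from
    ``seed``.  Only the trailing window is retained (the contract is that
    frozen-core and trajectory statistics depend on the recorded window
    only, not on the storage policy).
    """
    if total_steps < 1:
        raise ValueError(f"total_steps must be >= 1, got {total_steps}")
    if not (0.0 < update_fraction <= 1.0):
        raise ValueError(f"update_fraction must lie in (0, 1], got {update_fraction}")
    W = _as_csr(weights)
    n = W.shape[0]
    s0 = np.asarray(s0, dtype=np.int8)
    if s0.shape != (n,):
        raise ValueError(f"s0 must have shape ({n},), got {s0.shape}")
    b = np.zeros(n) if bias is None else np.asarray(bias, dtype=np.float64)
    if b.shape != (n,):
        raise ValueError(f"bias must have shape ({n},), got {b.shape}")
    n_update = max(1, int(round(update_fraction * n)))
    n_update = min(n_update, n)
    window = total_steps if record_window is None else min(record_window, total_steps)
    rec = simulate_threshold(
        W.indptr,
        W.indices,
        W.data,
        b,
        s0,
        int(total_steps),
        int(n_update),
        int(window),
        int(seed) % (2**31),
        np.int8(_zero_value(sign_variant)),
    )
    return StateTrajectory(
        states=rec,
        update_fraction=update_fraction,
        steps=total_steps,
        record_start=total_steps - window,
    )


def frozen_core_fraction(
    trajectory: StateTrajectory, window: Optional[Tuple[int, int]] = None
) -> float:
    """Fraction of nodes whose value is identical at every recorded step.

    ``window`` optionally restricts to a (start, stop) slice of the recorded
    states; the default uses every recorded state.
    """
    states = trajectory.states
    if window is not None:
        start, stop = window
        states = states[start:stop]
    if states.shape[0] == 0:
        raise ValueError("empty measurement window")
    frozen = np.all(states == states[0], axis=0)
    return float(frozen.mean())


def classify_convergence(frozen_fraction: float, qfp_threshold: float = 0.9) -> str:
    """``fixed_point`` at fraction 1, ``qfp`` above the threshold, else ``none``."""
    if not (0.0 <= frozen_fraction <= 1.0):
        raise ValueError(f"frozen_fraction must lie in [0, 1], got {frozen_fraction}")
    if frozen_fraction >= 1.0:
        return "fixed_point"
    if frozen_fraction >= qfp_threshold:
        return "qfp"
    return "none"


def simulate_convergence(
    weights,
    bias: Optional[np.ndarray] = None,
    s0: Optional[np.ndarray] = None,
    seed: int = 0,
    burn_in: int = DEFAULT_PROTOCOL["burn_in"],
    window: int = DEFAULT_PROTOCOL["window"],
    update_fraction: float = DEFAULT_PROTOCOL["update_fraction"],
    sign_variant: str = "zero",
    qfp_threshold: float = 0.9,
) -> ConvergenceSummary:
    """Run the standard frozen-core protocol on one network realization."""
    rng = np.random.default_rng(seed)
    n = weights.shape[0]
    if s0 is None:
        s0 = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
    kernel_seed = int(rng.integers(2**31))
    traj = run_dynamics(
        weights,
        s0,
        total_steps=burn_in + window,
        update_fraction=update_fraction,
        seed=kernel_seed,
        sign_variant=sign_variant,
        bias=bias,
        record_window=window,
    )
    ff = frozen_core_fraction(traj)
    return ConvergenceSummary(
        frozen_fraction=ff,
        classification=classify_convergence(ff, qfp_threshold),
        qfp_threshold=qfp_threshold,
        burn_in_steps=burn_in,
        window_steps=window,
    )


def convergence_probability(
    factory: Callable[[np.random.Generator], tuple],
    n_realizations: int,
    seed: int = 0,
    criterion: str = "qfp",
    return_fractions: bool = False,
    **protocol,
):
    """Estimate P(convergence) over independent realizations.

    ``factory(rng)`` must return ``(weights, bias)`` for one realization
    (``bias`` may be None).  Each realization gets an independent child seed
    for network, initial condition, and update stream.  ``criterion`` is
    ``"qfp"`` (frozen core >= threshold, fixed points included) or
    ``"fixed_point"`` (frozen core == 1).  Returns ``(p, se)`` with the
    binomial standard error, plus the per-realization frozen fractions when
    ``return_fractions`` is set.
    """
    if n_realizations < 1:
        raise ValueError(f"n_realizations must be >= 1, got {n_realizations}")
    if criterion not in ("qfp", "fixed_point"):
        raise ValueError(f"criterion must be 'qfp' or 'fixed_point', got {criterion!r}")
    children = np.random.SeedSequence(seed).spawn(n_realizations)
    hits = 0
    fractions = np.empty(n_realizations)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        weights, bias = factory(rng)
        summary = simulate_convergence(
            weights, bias=bias, seed=int(rng.integers(2**31)), **protocol
        )
        fractions[r] = summary.frozen_fraction
        if criterion == "qfp":
            hits += summary.classification in ("qfp", "fixed_point")
        else:
            hits += summary.classification == "fixed_point"
    p = hits / n_realizations
    se = float(np.sqrt(p * (1.0 - p) / n_realizations))
    if return_fractions:
        return p, se, fractions
    return p, se


def estimate_convergence_probability(
    params,
    n_realizations: int,
    seed: int = 0,
    criterion: str = "qfp",
    **protocol,
):
    """Convergence probability of a topology ensemble (see ``ensembles``).

    Each realization draws an independent topology, strengths, and initial
    condition, runs the standard protocol, and classifies the outcome.
    """
    from .ensembles import EnsembleParams, build_network

    if not isinstance(params, EnsembleParams):
        raise TypeError("params must be an EnsembleParams; for lumped-hub systems "
                        "use lumped_hub factories with convergence_probability")

    def factory(rng):
        return build_network(params, rng).weights, None

    return convergence_probability(
        factory, n_realizations, seed=seed, criterion=criterion, **protocol
    )
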