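"""Mean-field damage-spreading theory for driven threshold networks.

The open-loop lumped-hub system is a homogeneous binomial bulk (mean degree
``k_b``) driven by a clamped hub that reaches a fraction ``alpha`` of the
nodes with Gaussian strengths of scale ``sigma_h``.  Whether a single-bit
perturbation heals or spreads is governed by the derivative at the origin of
the one-step map of the normalized Hamming distance between two trajectories,

    grad_d = (2 k_b / pi) * sum_{k'>=0} P_Poisson(k'; k_b)
             * [ alpha * arctan(1 / sqrt(k' + sigma_h^2))
               + (1 - alpha) * arctan(1 / sqrt(k')) ],

where the undriven ``k' = 0`` term contributes its limiting value pi/2.
``grad_d < 1`` means damage heals and the drive suppresses chaos; the
critical hub strength ``sigma_crit(k_b, alpha)`` solves ``grad_d = 1``.  For
``alpha = 1`` and large ``k_b`` the sum collapses to the closed form
``2 k_b / (pi sqrt(k_b + sigma_h^2))``, giving an asymptotically linear
critical line ``sigma_crit ~ (2/pi) k_b``.

Closing the loop makes the hub a dynamic node; a converged bulk state is
consistent with the clamped hub value with probability one half, so the
closed-loop convergence probability is half the open-loop one provided the
hub does not flip before the bulk converges (``T_conv < T_flip``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.stats import poisson

from .lumped_hub import LumpedHubNetwork, assemble_system

__all__ = [
    "MFTPrediction",
    "exceedance_probability",
    "grad_d",
    "grad_d_asymptotic",
    "sigma_crit",
    "grad_d_monte_carlo_oracle",
    "grad_d_oracle_over_ensemble",
    "convergence_time",
    "hub_flip_probability",
    "flip_time",
    "closed_loop_stability_margin",
    "predict",
]

#: Poisson series truncated once the remaining tail mass drops below this.
POISSON_TAIL = 1e-12

#: |grad_d - 1| tolerance of the critical-strength root.
ROOT_TOL = 1e-8


@dataclass
class MFTPrediction:
    """Bundle of mean-field predictions for one parameter point."""

    grad_d: float
    sigma_crit: Optional[float]
    converges_open_loop: bool
    p_closed_loop: float
    T_conv: Optional[float]
    T_flip: float
    delta: float


def exceedance_probability(eta: float) -> float:
    """``Pr{|z1| > eta |z2|}`` for independent standard normals.

    The joint density of (|z1|, |z2|) is isotropic, so the probability is the
    angular fraction below the line |z2| = |z1|/eta: ``(2/pi) arctan(1/eta)``.
    ``eta = 0`` is the limiting value 1.
    """
    if eta < 0:
        raise ValueError(f"eta must be non-negative, got {eta}")
    if eta == 0:
        return 1.0
    return float(2.0 / np.pi * np.arctan(1.0 / eta))


def _poisson_grid(k_b: float):
    k_max = int(poisson.isf(POISSON_TAIL / 10.0, k_b)) + 10
    k = np.arange(k_max + 1)
    return k, poisson.pmf(k, k_b)


def _arctan_inv_sqrt(x: np.ndarray) -> np.ndarray:
    """arctan(1/sqrt(x)) elementwise with the x = 0 limit pi/2."""
    out = np.full(x.shape, np.pi / 2.0)
    pos = x > 0
    out[pos] = np.arctan(1.0 / np.sqrt(x[pos]))
    return out


def grad_d(k_b: float, sigma_h: float, alpha: float) -> float:
    """Damage-spreading derivative at the origin of the Hamming-distance map."""
    if k_b <= 0:
        raise ValueError(f"k_b must be positive, got {k_b}")
    if sigma_h < 0:
        raise ValueError(f"sigma_h must be >= 0, got {sigma_h}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    k, pmf = _poisson_grid(k_b)
    driven = _arctan_inv_sqrt(k + sigma_h**2)
    undriven = _arctan_inv_sqrt(k.astype(np.float64))
    series = float(np.sum(pmf * (alpha * driven + (1.0 - alpha) * undriven)))
    return 2.0 * k_b / np.pi * series


def grad_d_asymptotic(k_b: float, sigma_h: float) -> float:
    """Large-``k_b``, ``alpha = 1`` closed form ``2 k_b / (pi sqrt(k_b + sigma_h^2))``."""
    return float(2.0 * k_b / (np.pi * np.sqrt(k_b + sigma_h**2)))


def sigma_crit(k_b: float, alpha: float) -> Optional[float]:
    """Critical hub strength solving ``grad_d(k_b, sigma, alpha) = 1``.

    Returns 0 when the undriven bulk already converges, and None
    ("undefined") when no hub strength can suppress chaos — for sparse hubs
    there is a maximal ``k_b`` beyond which ``grad_d > 1`` for every
    ``sigma_h``.
    """
    if k_b <= 0:
        raise ValueError(f"k_b must be positive, got {k_b}")
    g0 = grad_d(k_b, 0.0, alpha)
    if g0 <= 1.0:
        return 0.0
    # sigma -> infinity limit: the driven term vanishes
    k, pmf = _poisson_grid(k_b)
    g_inf = 2.0 * k_b / np.pi * (1.0 - alpha) * float(
        np.sum(pmf * _arctan_inv_sqrt(k.astype(np.float64)))
    )
    if g_inf >= 1.0:
        return None
    hi = 1.0
    while grad_d(k_b, hi, alpha) > 1.0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable given the limit check
            return None
    root = brentq(lambda s: grad_d(k_b, s, alpha) - 1.0, 0.0, hi, xtol=1e-13, rtol=1e-15)
    assert abs(grad_d(k_b, root, alpha) - 1.0) < ROOT_TOL
    return float(root)


def grad_d_monte_carlo_oracle(
    lh: LumpedHubNetwork | sp.spmatrix,
    n_trials: int,
    seed: int = 0,
    bias: Optional[np.ndarray] = None,
):
    """Direct damage-spreading estimate of ``grad_d`` on one realization.

    Per trial: draw a random ±1 state, flip one random bit, advance both
    copies one synchronous step, and count differing output bits; the trial
    values average to ``N * Pr{single-bit damage spreads to a given row}``.
    Returns ``(estimate, standard_error)``.
    """
    if isinstance(lh, LumpedHubNetwork):
        system = assemble_system(lh, loop="open")
        W = system.weights
        bias = system.bias
    else:
        W = sp.csr_matrix(lh, dtype=np.float64)
    n = W.shape[0]
    b = np.zeros(n) if bias is None else np.asarray(bias, dtype=np.float64)
    W_csc = W.tocsc()
    rng = np.random.default_rng(seed)
    counts = np.empty(n_trials)
    for t in range(n_trials):
        s = rng.choice([-1.0, 1.0], size=n)
        flip = int(rng.integers(n))
        h = W @ s + b
        col = np.zeros(n)
        lo, hi = W_csc.indptr[flip], W_csc.indptr[flip + 1]
        col[W_csc.indices[lo:hi]] = W_csc.data[lo:hi]
        h_flipped = h - 2.0 * s[flip] * col
        counts[t] = np.count_nonzero(np.sign(h) != np.sign(h_flipped))
    est = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_trials)) if n_trials > 1 else np.inf
    return est, se


def grad_d_oracle_over_ensemble(
    params,
    n_bulk: int,
    n_networks: int,
    trials_per_network: int,
    seed: int = 0,
    mode: str = "sparse_gaussian",
):
    """Average the Monte-Carlo damage-spreading estimate over realizations."""
    from .lumped_hub import build_dense_gaussian, build_sparse_gaussian

    builder = build_sparse_gaussian if mode == "sparse_gaussian" else build_dense_gaussian
    children = np.random.SeedSequence(seed).spawn(n_networks)
    all_counts = []
    for child in children:
        rng = np.random.default_rng(child)
        lh = builder(params, n_bulk, rng)
        system = assemble_system(lh, loop="open")
        est, se = grad_d_monte_carlo_oracle(
            system.weights, trials_per_network, seed=int(rng.integers(2**31)),
            bias=system.bias,
        )
        all_counts.append((est, se))
    ests = np.array([e for e, _ in all_counts])
    # trials are i.i.d. across networks; pool the per-network means
    est = float(ests.mean())
    se = float(ests.std(ddof=1) / np.sqrt(n_networks)) if n_networks > 1 else all_counts[0][1]
    return est, se


def convergence_time(grad: float, n: int, delta: float) -> float:
    """Steps for a perturbation of size ``delta`` to contract below one node.

    Exponential healing at rate ``grad`` gives ``-ln(N delta) / ln(grad)``
    (natural logarithms).  Undefined for ``grad >= 1``.
    """
    if not (0.0 < grad < 1.0):
        raise ValueError(f"convergence time requires 0 < grad_d < 1, got {grad}")
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    return float(-np.log(n * delta) / np.log(grad))


def hub_flip_probability(delta: float, k_h: float, n: int) -> float:
    """Per-step probability that the hub flips after a ``delta`` perturbation.

    A perturbation flips one of the hub's ``k_h`` inputs with probability
    ``delta k_h / N``; a single flipped input changes the hub's sign with
    probability ``(2/pi) arctan(1/sqrt(k_h))``.
    """
    if not (0.0 <= delta < 1.0):
        raise ValueError(f"delta must lie in [0, 1), got {delta}")
    if k_h < 1:
        raise ValueError(f"k_h must be >= 1, got {k_h}")
    return float(delta * k_h / n * exceedance_probability(np.sqrt(k_h)))


def flip_time(n: int, k_h: float, delta: float) -> float:
    """Coarse typical hub flipping time ``N / (k_h delta)`` (arctan factor dropped)."""
    if k_h < 1:
        raise ValueError(f"k_h must be >= 1, got {k_h}")
    if delta <= 0:
        return np.inf
    return float(n / (k_h * delta))


def closed_loop_stability_margin(grad: float, n: int, k_h: float, delta: float) -> dict:
    """Check that the bulk converges before the hub can flip.

    Compares ``T_conv < T_flip`` and, near criticality, the margin
    ``1 - grad_d`` against the bound ``(k_h delta / N) ln(delta N)``.
    Returns a dict with ``status`` ("stable" or "marginal"), the margin, the
    near-critical bound, and both time scales.
    """
    if grad >= 1.0:
        raise ValueError("closed-loop analysis requires an open-loop convergent system")
    t_conv = convergence_time(grad, n, delta)
    t_flip = flip_time(n, k_h, delta)
    margin = 1.0 - grad
    bound = k_h * delta / n * np.log(delta * n)
    stable = (t_conv < t_flip) and (margin > bound)
    return {
        "status": "stable" if stable else "marginal",
        "margin": float(margin),
        "bound": float(bound),
        "T_conv": float(t_conv),
        "T_flip": float(t_flip),
    }


def predict(params, n: int, delta: float = 0.1) -> MFTPrediction:
    """Full mean-field prediction for a lumped-hub parameter point.

    ``p_closed_loop`` applies the factor-of-half rule: away from criticality
    the closed loop converges iff the open loop does, with probability 1/2
    from the hub sign-consistency condition.
    """
    g = grad_d(params.k_b, params.sigma_h, params.alpha)
    sc = sigma_crit(params.k_b, params.alpha)
    converges = g < 1.0
    k_h = params.k_h if params.k_h >= 1 else max(1.0, params.m * params.k_b)
    t_conv = convergence_time(g, n, delta) if converges else None
    return MFTPrediction(
        grad_d=g,
        sigma_crit=sc,
        converges_open_loop=converges,
        p_closed_loop=0.5 if converges else 0.0,
        T_conv=t_conv,
        T_flip=flip_time(n, k_h, delta),
        delta=delta,
    )
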