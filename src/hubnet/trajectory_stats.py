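"""Dimensionality and temporal-correlation statistics of trajectories.

Used to compare non-converging dynamics between original heterogeneous
ensembles and their lumped-hub reductions: the participation ratio
``(tr C)^2 / tr(C^2)`` of the state covariance measures the effective
dimensionality explored, and the node-averaged autocorrelation profile with
an exponential fit over short lags measures the decorrelation speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .dynamics import StateTrajectory

__all__ = [
    "TrajectoryStatistics",
    "participation_ratio",
    "autocorrelation_profile",
    "asymptotic_autocorrelation",
    "exponential_fit",
    "summarize_trajectory",
    "ensemble_autocorrelation",
]

#: Trajectories whose large-lag autocorrelation exceeds this are treated as
#: (partially) frozen and excluded from ensemble correlation averages.
ASYMPTOTIC_THRESHOLD = 0.3


@dataclass
class TrajectoryStatistics:
    participation_ratio: float
    autocorrelation: np.ndarray
    asymptotic_autocorr: float
    exp_fit_rate: float


def _states(trajectory) -> np.ndarray:
    if isinstance(trajectory, StateTrajectory):
        return trajectory.states.astype(np.float64)
    return np.asarray(trajectory, dtype=np.float64)


def participation_ratio(trajectory) -> float:
    """``(tr C)^2 / tr(C^2)`` for the state covariance C over the segment.

    Equals the number of equally weighted covariance eigendirections: 1 for
    rank-one dynamics, up to N for isotropic exploration.  A constant
    trajectory has zero covariance; the ratio is undefined and reported as
    NaN.
    """
    X = _states(trajectory)  # (time, nodes)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 recorded states")
    X = X - X.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(X, compute_uv=False)
    ev = sv**2  # proportional to covariance eigenvalues; the scale cancels
    tr = ev.sum()
    if tr == 0.0:
        return float("nan")
    return float(tr**2 / np.sum(ev**2))


def autocorrelation_profile(
    trajectory, max_lag: int, subtract_mean: bool = True
) -> np.ndarray:
    """Node- and time-averaged state autocorrelation over lags 0..max_lag.

    Normalized to 1 at lag 0.  ``subtract_mean`` removes each node's
    temporal mean first (the standard definition); the raw-product variant
    is available for comparison with conventions that skip centering.  A
    frozen trajectory has zero centered variance and returns the all-ones
    profile (raw convention) so callers can filter it out.
    """
    X = _states(trajectory)
    T = X.shape[0]
    if max_lag < 0 or T <= max_lag + 1:
        raise ValueError(f"trajectory of {T} states too short for max_lag={max_lag}")
    if subtract_mean:
        X = X - X.mean(axis=0, keepdims=True)
    denom = np.mean(X * X)
    if denom == 0.0:
        return np.ones(max_lag + 1)
    ac = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        ac[lag] = np.mean(X[: T - lag] * X[lag:]) / denom
    return ac


def asymptotic_autocorrelation(profile: np.ndarray) -> float:
    """Mean autocorrelation over the last quarter of computed lags."""
    profile = np.asarray(profile)
    tail = max(1, profile.size // 4)
    return float(profile[-tail:].mean())


def exponential_fit(profile: np.ndarray, lag_range: Tuple[int, int] = (0, 5)) -> float:
    """Decay rate from a log-linear least-squares fit over the given lags.

    Fits ``log ac(l) ~ -rate * l`` using only the lags where the profile is
    positive (at least two are required).
    """
    profile = np.asarray(profile, dtype=np.float64)
    lo, hi = lag_range
    lags = np.arange(lo, min(hi, profile.size - 1) + 1)
    vals = profile[lags]
    keep = vals > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 positive autocorrelation values in the fit range")
    slope, _ = np.polyfit(lags[keep], np.log(vals[keep]), 1)
    return float(-slope)


def summarize_trajectory(
    trajectory, max_lag: int = 20, subtract_mean: bool = True
) -> TrajectoryStatistics:
    profile = autocorrelation_profile(trajectory, max_lag, subtract_mean)
    return TrajectoryStatistics(
        participation_ratio=participation_ratio(trajectory),
        autocorrelation=profile,
        asymptotic_autocorr=asymptotic_autocorrelation(profile),
        exp_fit_rate=exponential_fit(profile),
    )


def ensemble_autocorrelation(
    trajectories: Sequence,
    max_lag: int = 20,
    threshold: float = ASYMPTOTIC_THRESHOLD,
    subtract_mean: bool = True,
) -> Optional[np.ndarray]:
    """Mean autocorrelation profile over non-frozen trajectories.

    Profiles whose asymptotic (large-lag) autocorrelation exceeds the
    threshold are excluded before averaging; returns None when the filter
    removes everything.
    """
    kept = []
    for traj in trajectories:
        profile = autocorrelation_profile(traj, max_lag, subtract_mean)
        if asymptotic_autocorrelation(profile) < threshold:
            kept.append(profile)
    if not kept:
        return None
    return np.mean(kept, axis=0)
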