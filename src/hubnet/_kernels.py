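"""Numba kernels for the inner simulation loops.

The asynchronous update loop touches only a small random subset of nodes per
step, so the work per step is tiny; a compiled kernel removes the Python
per-step overhead that would otherwise dominate ensemble sweeps.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_threshold(
    indptr,
    indices,
    data,
    bias,
    s0,
    total_steps,
    n_update,
    window,
    seed,
    zero_value,
):
    """Run threshold dynamics and record the trailing window of states.

    Parameters
    ----------
    indptr, indices, data : CSR arrays of the weight matrix (row = inputs).
    bias : float64[n]
        Constant external input added inside the sign (zero for plain
        recurrent dynamics; the clamped-hub drive in the open-loop setting).
    s0 : int8[n]
        Initial state with entries in {-1, 0, +1}.
    total_steps : int
        Number of update steps.
    n_update : int
        Nodes updated per step, drawn uniformly without replacement, fresh
        each step.  ``n_update == n`` gives the synchronous parallel update.
    window : int
        Trailing steps to record; the returned array holds ``window + 1``
        states (the state when the window opens plus one per step inside).
    seed : int
        Seed for the update-subset stream (< 2**31).
    zero_value : int8
        Value assigned when a node's input sums to exactly zero: 0 for the
        pruning convention, +1 for the convention that keeps source nodes
        acting as a constant drive.

    Updates within a step are simultaneous: all selected nodes read the
    current state, then write together.
    """
    np.random.seed(seed)
    n = s0.shape[0]
    s = s0.copy()
    rec = np.empty((window + 1, n), dtype=np.int8)
    start = total_steps - window
    if start == 0:
        rec[0] = s
    perm = np.arange(n)
    new_vals = np.empty(n_update, dtype=np.int8)
    for step in range(1, total_steps + 1):
        # partial Fisher-Yates: uniform subset without replacement
        for j in range(n_update):
            r = j + np.random.randint(0, n - j)
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp
        for j in range(n_update):
            i = perm[j]
            acc = bias[i]
            for k in range(indptr[i], indptr[i + 1]):
                acc += data[k] * s[indices[k]]
            if acc > 0.0:
                new_vals[j] = 1
            elif acc < 0.0:
                new_vals[j] = -1
            else:
                new_vals[j] = zero_value
        for j in range(n_update):
            s[perm[j]] = new_vals[j]
        if step >= start:
            rec[step - start] = s
    return rec
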