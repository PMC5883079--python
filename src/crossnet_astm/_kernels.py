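"""Numba-compiled inner loops for iterative recording rules.

All kernels operate on the flattened representation: ``X[q, i, :]`` holds the
states of cell i's M neighbors in frame q (int8, +/-1), ``T[q, i]`` the target
state of cell i in frame q+1 (wrapping), and ``W[i, :]`` the weight vector of
cell i aligned with the neighbor ordering.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True)
def _epoch_agd(W, X, T, eta):
    """One analog-gradient-descent epoch; returns max |error| seen (pre-update)."""
    Q, N, M = X.shape
    max_err = 0.0
    for q in range(Q):
        for i in range(N):
            a = 0.0
            for j in range(M):
                a += W[i, j] * X[q, i, j]
            e = a - T[q, i]
            ae = abs(e)
            if ae > max_err:
                max_err = ae
            if e != 0.0:
                step = eta * e
                for j in range(M):
                    W[i, j] -= step * X[q, i, j]
    return max_err


@njit(fastmath=True)
def agd_train(W, X, T, eta, tol, max_epochs, stall_window, stall_start):
    """Analog delta-rule training loop with an extrapolative early stop.

    Presents the Q frame pairs in movie order, updating weights after every
    pair.  Converged when every per-presentation error magnitude within one
    epoch falls below ``tol``.  The late-time error decay of this LMS-type
    iteration is geometric with a rate that only slows as fast transients die
    out; therefore, if a projection using the *current* (optimistic) rate says
    the tolerance cannot be reached within the epoch budget, further iteration
    is provably futile and the loop exits early, reporting non-convergence.

    Returns (epochs_run, final_max_error, converged, early_stopped).
    """
    prev_err = -1.0
    err = np.inf
    epoch = 0
    while epoch < max_epochs:
        err = _epoch_agd(W, X, T, eta)
        epoch += 1
        if err < tol:
            return epoch, err, True, False
        if stall_window > 0 and epoch >= stall_start and epoch % stall_window == 0:
            if prev_err >= 0.0:
                if err >= prev_err:
                    return epoch, err, False, True  # plateau or divergence
                rate = (np.log(prev_err) - np.log(err)) / stall_window
                needed = np.log(err / tol) / rate
                if needed > (max_epochs - epoch):
                    return epoch, err, False, True
            prev_err = err
    return epoch, err, False, False


@njit(fastmath=True)
def dgd_train(W, X, T, eta, D, max_epochs):
    """Discrete (gap) gradient-descent training loop.

    Error is ternary: e = S - t with S = sgn(a - D*t), sgn(0) = +1, so
    e in {-2, 0, 2}; weight update is the delta rule with this error.
    Converged when a full epoch produces zero updates, which implies
    a_i * t > D for every cell and pair.

    Returns (epochs_run, errors_in_last_epoch, converged).
    """
    Q, N, M = X.shape
    n_err = -1
    for epoch in range(1, max_epochs + 1):
        n_err = 0
        for q in range(Q):
            for i in range(N):
                a = 0.0
                for j in range(M):
                    a += W[i, j] * X[q, i, j]
                t = T[q, i]
                arg = a - D * t
                S = 1.0 if arg >= 0.0 else -1.0
                e = S - t
                if e != 0.0:
                    n_err += 1
                    step = eta * e
                    for j in range(M):
                        W[i, j] -= step * X[q, i, j]
        if n_err == 0:
            return epoch, 0, True
    return max_epochs, n_err, False


@njit(fastmath=True)
def sync_loop(W, nbr, start, steps):
    """Iterated synchronous sign map; returns the final frame (flat int8).

    sgn(0) = +1, matching the package-wide convention.
    """
    N, M = W.shape
    cur = start.copy()
    nxt = np.empty(N, dtype=np.int8)
    for _ in range(steps):
        for i in range(N):
            a = 0.0
            for j in range(M):
                a += W[i, j] * cur[nbr[i, j]]
            nxt[i] = 1 if a >= 0.0 else -1
        cur, nxt = nxt, cur
    return cur


@njit(fastmath=True)
def hildreth_batch(G, kappa, max_sweeps, feas_tol, dual_rtol, feasibility_only):
    """Dual coordinate ascent (Hildreth) for the per-cell minimum-norm QP.

    For each cell the primal problem is  min ||w||^2 / 2  s.t.  A w >= kappa
    (A is the Q x M margin-constraint matrix); the dual is
    min_{lam >= 0}  lam' G lam / 2 - kappa * sum(lam)  with  G = A A'.
    The kernel maintains v = G lam, which equals the vector of achieved
    margins A w at the current dual point, so feasibility and convergence
    are read off directly.

    Parameters
    ----------
    G : (N, Q, Q) float64 Gram matrices, one per cell.
    feasibility_only : if nonzero, stop a cell as soon as its margins are all
        >= kappa - feas_tol (a feasible, not necessarily minimum-norm, point);
        retrieval outcomes are identical for any feasible point, so capacity
        experiments may use this profile.

    Returns
    -------
    lam : (N, Q) dual variables (w_i = A_i' lam_i).
    min_margin : (N,) smallest achieved margin per cell.
    converged : (N,) uint8 flags (dual converged or feasibility reached).
    sweeps : (N,) sweeps used per cell.
    """
    N, Q, _ = G.shape
    lam = np.zeros((N, Q))
    min_margin = np.empty(N)
    converged = np.zeros(N, dtype=np.uint8)
    sweeps_used = np.zeros(N, dtype=np.int64)
    for i in range(N):
        g = G[i]
        li = lam[i]
        v = np.zeros(Q)
        mm = 0.0
        for sweep in range(1, max_sweeps + 1):
            max_step = 0.0
            for q in range(Q):
                gqq = g[q, q]
                if gqq <= 0.0:
                    continue
                new = li[q] + (kappa - v[q]) / gqq
                if new < 0.0:
                    new = 0.0
                d = new - li[q]
                if d != 0.0:
                    li[q] = new
                    for p in range(Q):
                        v[p] += d * g[p, q]
                    ad = abs(d)
                    if ad > max_step:
                        max_step = ad
            mm = v[0]
            for q in range(1, Q):
                if v[q] < mm:
                    mm = v[q]
            feasible = mm >= kappa - feas_tol
            if feasibility_only and feasible:
                converged[i] = 1
                sweeps_used[i] = sweep
                break
            if feasible and max_step <= dual_rtol:
                converged[i] = 1
                sweeps_used[i] = sweep
                break
        else:
            sweeps_used[i] = max_sweeps
        min_margin[i] = mm
    return lam, min_margin, converged, sweeps_used
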