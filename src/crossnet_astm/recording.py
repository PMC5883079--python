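"""The four movie-recording rules that set the synaptic weights.

Given a closed-loop movie of Q frames on a toroidal grid, each rule produces
one weight vector per cell, aligned with the grid's neighbor ordering, such
that (ideally) the synchronous readout maps every frame onto its successor:

* ``record_hebb`` — one-shot outer-product (Hebbian) recording,
  w_ij = (1/Q) sum_q s_i^(q+1) s_j^(q).
* ``record_qp``  — minimum-Euclidean-norm weights under the per-pair margin
  constraints s_i^(q+1) sum_j w_ij s_j^(q) >= kappa, solved independently per
  cell (the joint problem is block-diagonal over cells).
* ``record_agd`` — analog gradient descent (delta rule): the error is the
  analog mismatch a_i - s_i^(q+1), iterated over epochs of pair presentations.
* ``record_dgd`` — discrete gradient descent with a gap [-D, +D]: the error is
  ternary in {-2, 0, 2} and vanishes once a_i s_i^(q+1) > D, so convergence
  certifies exact one-step prediction with a finite margin.

Sign convention: sgn(0) = +1 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .movie_io import Movie
from .topology import ConfigurationError, TorusGrid

RULES = ("hebb", "qp", "agd", "dgd")

_DEFAULT_ETA = {"agd": 0.001, "dgd": 0.005}


@dataclass(frozen=True)
class RecorderParams:
    """Configuration of a recording rule.

    Parameters
    ----------
    rule : {'hebb', 'qp', 'agd', 'dgd'}
    eta : float, optional
        Learning rate for the gradient-descent rules.  Defaults to the
        rule-specific value (0.001 analog, 0.005 discrete).
    D : float
        Gap half-width of the discrete rule.  Rescaling D before recording
        rescales all weights proportionally without changing retrieval.
    kappa : float
        Margin of the QP constraints.  Any kappa > 0 is equivalent up to a
        global weight scale under the sign readout; a strict ">0" constraint
        would leave the minimum-norm problem without an attained minimum.
    agd_tol : float
        Analog-rule stop tolerance on the largest per-presentation |error|.
    max_epochs : int
        Epoch cap for the iterative rules.
    qp_tol : float
        Post-hoc feasibility tolerance on the achieved QP margins.
    qp_max_sweeps : int
        Cap on dual coordinate-ascent sweeps per cell.
    qp_feasibility_only : bool
        Stop each cell's QP at the first feasible point instead of iterating
        to the minimum-norm optimum.  Retrieval outcomes are identical for
        any feasible point, so capacity scans may enable this profile; noise
        studies must keep it off.
    agd_stall_window, agd_stall_start : int
        Epoch interval / first epoch for the analog rule's extrapolative
        early stop (0 window disables it).
    """

    rule: str = "dgd"
    eta: float | None = None
    D: float = 1.0
    kappa: float = 1.0
    agd_tol: float = 0.1
    max_epochs: int = 100_000
    qp_tol: float = 1e-6
    qp_max_sweeps: int = 3000
    qp_feasibility_only: bool = False
    qp_dual_rtol: float = 1e-10
    agd_stall_window: int = 500
    agd_stall_start: int = 2000

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ConfigurationError(f"unknown recording rule {self.rule!r}; choose from {RULES}")
        if self.eta is not None and self.eta <= 0:
            raise ConfigurationError("learning rate eta must be positive")
        if self.D <= 0 or self.kappa <= 0 or self.agd_tol <= 0:
            raise ConfigurationError("D, kappa and agd_tol must be positive")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")

    @property
    def learning_rate(self) -> float:
        if self.eta is not None:
            return self.eta
        return _DEFAULT_ETA.get(self.rule, 0.001)


@dataclass(frozen=True)
class WeightSet:
    """Per-cell synaptic weight vectors on a grid.

    ``W[i, :]`` is cell i's length-M weight vector, aligned with
    ``grid.neighbor_table[i]``.
    """

    grid: TorusGrid
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.shape != (self.grid.N, self.grid.M):
            raise ConfigurationError(
                f"weight array shape {W.shape} does not match grid (N={self.grid.N}, M={self.grid.M})"
            )
        if not np.isfinite(W).all():
            raise ConfigurationError("weights must be finite")
        object.__setattr__(self, "W", W)

    def rms(self) -> float:
        """Global r.m.s. of the weight distribution."""
        return float(np.sqrt(np.mean(self.W**2)))


@dataclass(frozen=True)
class ConvergenceReport:
    converged: bool
    epochs_run: int
    final_max_error: float
    early_stopped: bool = False


@dataclass(frozen=True)
class QPReport:
    """Per-cell feasibility outcome of the minimum-norm recording."""

    feasible: bool
    infeasible_cells: np.ndarray
    min_margin: float
    sweeps: int


def _check_pair(movie: Movie, grid: TorusGrid) -> None:
    if movie.shape != (grid.H, grid.W):
        raise ConfigurationError(
            f"movie frames {movie.shape} do not match grid {(grid.H, grid.W)}"
        )


def pair_tensors(movie: Movie, grid: TorusGrid) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor-state tensor X[q,i,:] and target matrix T[q,i] for all Q pairs.

    Pair q maps frame q onto frame (q+1) mod Q — the closed loop contributes
    the wrap-around pair (Q -> 1).
    """
    _check_pair(movie, grid)
    S = movie.flat()  # (Q, N) int8
    X = np.ascontiguousarray(S[:, grid.neighbor_table])  # (Q, N, M)
    T = np.ascontiguousarray(np.roll(S, -1, axis=0))
    return X, T


def record_hebb(movie: Movie, grid: TorusGrid) -> WeightSet:
    """Hebbian outer-product recording: w_ij = (1/Q) sum_q s_i^(q+1) s_j^(q)."""
    _check_pair(movie, grid)
    S = movie.flat().astype(np.float64)
    nbr = grid.neighbor_table
    W = np.zeros((grid.N, grid.M))
    for q in range(movie.Q):
        nxt = S[(q + 1) % movie.Q]
        W += nxt[:, None] * S[q][nbr]
    W /= movie.Q
    return WeightSet(grid=grid, W=W)


def record_qp(
    movie: Movie, grid: TorusGrid, params: RecorderParams | None = None
) -> tuple[WeightSet, QPReport]:
    """Minimum-norm weights under per-pair margin constraints, per cell.

    Cell i's constraint matrix has rows a_q = s_i^(q+1) * s_nbr(i)^(q); the
    minimum-norm solution is w_i = A_i' lam_i with lam_i >= 0 solving the
    dual, found by cyclic coordinate ascent.  Cells whose constraint systems
    are infeasible (frame pairs not linearly separable with the margin) are
    flagged in the report; their best-effort weights are still returned.
    """
    params = params or RecorderParams(rule="qp")
    X, T = pair_tensors(movie, grid)
    # A[q, i, :] = T[q, i] * X[q, i, :]; per-cell Gram G_i = A_i A_i'.
    A = (T[:, :, None] * X).astype(np.float32)  # (Q, N, M)
    Ai = np.ascontiguousarray(A.transpose(1, 0, 2))  # (N, Q, M)
    G = (Ai @ Ai.transpose(0, 2, 1)).astype(np.float64)  # (N, Q, Q)
    lam, min_margin, conv, sweeps = _kernels.hildreth_batch(
        G,
        params.kappa,
        params.qp_max_sweeps,
        params.qp_tol,
        params.qp_dual_rtol * params.kappa,
        1 if params.qp_feasibility_only else 0,
    )
    W = np.einsum("nq,nqm->nm", lam, Ai.astype(np.float64))
    bad = np.flatnonzero(min_margin < params.kappa - max(params.qp_tol, 1e-9))
    report = QPReport(
        feasible=bad.size == 0,
        infeasible_cells=bad,
        min_margin=float(min_margin.min()),
        sweeps=int(sweeps.max()),
    )
    return WeightSet(grid=grid, W=W), report


def record_agd(
    movie: Movie, grid: TorusGrid, params: RecorderParams | None = None
) -> tuple[WeightSet, ConvergenceReport]:
    """Analog gradient-descent recording (delta rule), zero-initialised.

    Pairs are presented in movie order within each epoch with immediate
    updates (stochastic gradient descent with batch size one frame pair);
    iteration stops when all error magnitudes drop below ``agd_tol`` or at
    ``max_epochs``, whichever comes first.
    """
    params = params or RecorderParams(rule="agd")
    X, T = pair_tensors(movie, grid)
    W = np.zeros((grid.N, grid.M))
    eta = params.eta if params.eta is not None else _DEFAULT_ETA["agd"]
    epochs, err, converged, early = _kernels.agd_train(
        W,
        X,
        T.astype(np.float64),
        eta,
        params.agd_tol,
        params.max_epochs,
        params.agd_stall_window,
        params.agd_stall_start,
    )
    return WeightSet(grid=grid, W=W), ConvergenceReport(
        converged=bool(converged),
        epochs_run=int(epochs),
        final_max_error=float(err),
        early_stopped=bool(early),
    )


def record_dgd(
    movie: Movie, grid: TorusGrid, params: RecorderParams | None = None
) -> tuple[WeightSet, ConvergenceReport]:
    """Discrete gradient-descent recording with gap D, zero-initialised.

    On convergence (a full epoch with zero updates) every recorded pair
    satisfies a_i s_i^(q+1) > D > 0, so synchronous retrieval reproduces all
    recorded transitions exactly.
    """
    params = params or RecorderParams(rule="dgd")
    X, T = pair_tensors(movie, grid)
    W = np.zeros((grid.N, grid.M))
    eta = params.eta if params.eta is not None else _DEFAULT_ETA["dgd"]
    epochs, n_err, converged = _kernels.dgd_train(
        W, X, T.astype(np.float64), eta, params.D, params.max_epochs
    )
    return WeightSet(grid=grid, W=W), ConvergenceReport(
        converged=bool(converged),
        epochs_run=int(epochs),
        final_max_error=float(n_err),
    )


def record(
    movie: Movie, grid: TorusGrid, params: RecorderParams
) -> tuple[WeightSet, ConvergenceReport | QPReport | None]:
    """Dispatch on ``params.rule``; Hebb returns a ``None`` report."""
    if params.rule == "hebb":
        return record_hebb(movie, grid), None
    if params.rule == "qp":
        return record_qp(movie, grid, params)
    if params.rule == "agd":
        return record_agd(movie, grid, params)
    return record_dgd(movie, grid, params)


def recording_succeeded(report: ConvergenceReport | QPReport | None) -> bool:
    """Whether a recording attempt achieved its rule's success criterion."""
    if report is None:
        return True  # Hebb always completes in one pass
    if isinstance(report, QPReport):
        return report.feasible
    return report.converged


# ---------------------------------------------------------------------------
# Serialization


def save_weights_csv(path: str | Path, ws: WeightSet) -> None:
    """CSV rows: cell, neighbor rank, row offset, col offset, weight."""
    g = ws.grid
    h = (g.m - 1) // 2
    offs = [(dr, dc) for dr in range(-h, h + 1) for dc in range(-h, h + 1) if (dr, dc) != (0, 0)]
    with open(path, "w") as fh:
        fh.write(f"# H={g.H} W={g.W} m={g.m}\ncell,rank,dr,dc,weight\n")
        for i in range(g.N):
            for k, (dr, dc) in enumerate(offs):
                fh.write(f"{i},{k},{dr},{dc},{float(ws.W[i, k])!r}\n")


def load_weights_csv(path: str | Path) -> WeightSet:
    from .topology import build_grid

    with open(path) as fh:
        header = fh.readline()
        kv = dict(tok.split("=") for tok in header.lstrip("# ").split())
        grid = build_grid(int(kv["H"]), int(kv["W"]), int(kv["m"]))
        fh.readline()  # column names
        W = np.zeros((grid.N, grid.M))
        for line in fh:
            cell, rank, _, _, w = line.split(",")
            W[int(cell), int(rank)] = float(w)
    return WeightSet(grid=grid, W=W)


def save_weights_npz(path: str | Path, ws: WeightSet) -> None:
    np.savez_compressed(path, H=ws.grid.H, W_dim=ws.grid.W, m=ws.grid.m, weights=ws.W)


def load_weights_npz(path: str | Path) -> WeightSet:
    from .topology import build_grid

    with np.load(path) as z:
        grid = build_grid(int(z["H"]), int(z["W_dim"]), int(z["m"]))
        return WeightSet(grid=grid, W=z["weights"])
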