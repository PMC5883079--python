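"""Globally-synchronous readout dynamics and movie-recovery scoring.

One synchronous step computes every cell's local field
I_i = sum_j w_ij V0 s_j over its M neighbors and applies the sharp
activation V_i = V0 sgn I_i (sgn(0) = +1).  Since only the sign is stored,
the output amplitude V0 rescales analog levels without affecting retrieval;
frames remain spin-valued {-1, +1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import WeightSet
from .topology import ConfigurationError


@dataclass(frozen=True)
class RetrievalParams:
    """V0 is the neural cell output amplitude; steps the number of updates."""

    V0: float = 1.0
    steps: int = 1

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ConfigurationError("V0 must be positive")
        if self.steps < 1:
            raise ConfigurationError("steps must be >= 1")


@dataclass(frozen=True)
class RetrievalTrace:
    """Frames produced by iterated synchronous steps.

    ``frames[0]`` is the input frame; ``frames[k]`` the k-th update.  If a
    reference movie was supplied, ``hamming[k]`` counts pixel mismatches of
    frames[k] against the reference frame expected at step k.
    """

    frames: np.ndarray
    hamming: np.ndarray | None = None

    @property
    def final(self) -> np.ndarray:
        return self.frames[-1]


def _flat_frame(ws: WeightSet, frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.shape != (ws.grid.H, ws.grid.W):
        raise ConfigurationError(
            f"frame shape {frame.shape} does not match grid {(ws.grid.H, ws.grid.W)}"
        )
    return frame.reshape(-1)


def local_fields(ws: WeightSet, frame: np.ndarray, V0: float = 1.0) -> np.ndarray:
    """Local fields I_i = sum_j w_ij V0 s_j, returned as an H x W raster."""
    s = _flat_frame(ws, frame)
    I = (ws.W * (V0 * s[ws.grid.neighbor_table])).sum(axis=1)
    return I.reshape(ws.grid.H, ws.grid.W)


def step_sync(ws: WeightSet, frame: np.ndarray, params: RetrievalParams | None = None) -> np.ndarray:
    """One synchronous update: output pixel = sgn(I_i), with sgn(0) = +1."""
    V0 = params.V0 if params is not None else 1.0
    I = local_fields(ws, frame, V0)
    return np.where(I >= 0.0, 1, -1).astype(np.int8)


def retrieve(
    ws: WeightSet,
    start: np.ndarray,
    steps: int,
    reference: np.ndarray | None = None,
) -> RetrievalTrace:
    """Iterate ``steps`` synchronous updates from ``start``.

    ``reference``, if given, is a (steps+1, H, W) stack of expected frames
    (element 0 aligned with the start frame) used to fill the per-step
    Hamming error; retrieval itself never consults it.
    """
    frames = np.empty((steps + 1, ws.grid.H, ws.grid.W), dtype=np.int8)
    frames[0] = np.asarray(start, dtype=np.int8)
    for k in range(steps):
        frames[k + 1] = step_sync(ws, frames[k])
    hamming = None
    if reference is not None:
        reference = np.asarray(reference)
        hamming = (frames != reference[: steps + 1]).reshape(steps + 1, -1).sum(axis=1)
    return RetrievalTrace(frames=frames, hamming=hamming)


def retrieve_loop(ws: WeightSet, start: np.ndarray, Q: int) -> np.ndarray:
    """Run one full closed loop (Q steps) and return only the final frame.

    Equivalent to ``retrieve(...).final`` but implemented as a compiled
    loop, which matters in Monte-Carlo sweeps with thousands of readouts.
    """
    from . import _kernels

    start = np.ascontiguousarray(np.asarray(start, dtype=np.int8).reshape(-1))
    if start.size != ws.grid.N:
        raise ConfigurationError("start frame does not match the grid")
    final = _kernels.sync_loop(ws.W, ws.grid.neighbor_table, start, Q)
    return final.reshape(ws.grid.H, ws.grid.W)


def evaluate_recovery(
    trace: RetrievalTrace | np.ndarray,
    reference: np.ndarray,
    tolerance: float = 0.0,
) -> tuple[bool, float]:
    """Score a retrieval by its final frame against a reference frame.

    Returns (success, error_fraction) with
    error_fraction = Hamming(final, reference) / N and success iff
    error_fraction <= tolerance (boundary inclusive).
    """
    if not 0.0 <= tolerance < 1.0:
        raise ConfigurationError("tolerance must lie in [0, 1)")
    final = trace.final if isinstance(trace, RetrievalTrace) else np.asarray(trace)
    reference = np.asarray(reference)
    err = float((final != reference).mean())
    return err <= tolerance, err
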