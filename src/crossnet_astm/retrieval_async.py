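"""Asynchronous spiking readout with leaky integrate-and-fire cells.

This module demonstrates the retrieval phenomenology of the memory when run
without a global clock: the input frame is applied at t = 0 as simultaneous
spikes — positive-polarity pulses from the frame's active (+1) pixels and
negative-polarity pulses from the inactive ones, matching the zero-centered
differential operation in which every cell drives the crossbar with one of
two opposite voltages.  Each spike injects the stereotyped current waveform

    g(t) = C sin(t / tau) exp(-t / (2 tau)),   t >= 0,

weighted by the recorded synapses (and signed by the spike polarity), into
the spiking cell's neighbors.  A cell fires a positive spike when its leaky
membrane potential crosses +theta and a negative spike when it crosses
-theta; either way it resets and turns refractory.  Spike times of cells
belonging to one frame spread ("jitter") because of accumulated residual
potentials, but as long as the recorded load is well below capacity the
spread stays clustered frame by frame instead of accumulating, and the
window-averaged content of each frame is reproduced correctly.

Quantitative results live in the synchronous mode (:mod:`.retrieval_sync`);
this module's defaults are chosen only so that a cell receiving the
correctly-signed mean drive fires within about one spike duration, and every
constant is configuration-exposed.  An optional global clock (periodic
simultaneous threshold release) reduces the dynamics to the synchronous map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import WeightSet
from .topology import ConfigurationError


@dataclass(frozen=True)
class LIFParams:
    """Spike waveform and leaky integrate-and-fire constants.

    ``C`` and ``tau`` scale the spike amplitude and duration; neither is
    critical for the demonstrated effects.  ``theta`` is the (symmetric)
    firing threshold relative to the drive produced by a unit local field.
    ``kernel`` selects the decay envelope reading: 'half-exp' for
    exp(-t/(2 tau)) (default) or 'gaussian' for exp(-t^2/tau).
    ``clock_period``, if set, replaces free-running threshold crossings with
    a global clock: at each tick every cell emits a spike whose polarity is
    the sign of its accumulated potential (sign of 0 counts as +1).
    """

    C: float = 1.0
    tau: float = 1.0
    theta: float = 0.45
    tau_m: float = 8.0
    refractory: float = 2.0
    dt: float = 0.02
    T: float = 60.0
    kernel: str = "half-exp"
    clock_period: float | None = None

    def __post_init__(self) -> None:
        if min(self.C, self.tau, self.theta, self.tau_m, self.dt, self.T) <= 0:
            raise ConfigurationError("C, tau, theta, tau_m, dt, T must all be positive")
        if self.refractory < 0:
            raise ConfigurationError("refractory must be nonnegative")
        if self.dt > 0.25 * self.tau:
            raise ConfigurationError("dt must be well below tau")
        if self.kernel not in ("half-exp", "gaussian"):
            raise ConfigurationError("kernel must be 'half-exp' or 'gaussian'")


@dataclass(frozen=True)
class SpikeRaster:
    """Per-cell spike times and polarities, plus the simulated horizon T."""

    times: list[np.ndarray]
    polarities: list[np.ndarray]
    T: float

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.times))

    def all_times(self, polarity: int | None = None) -> np.ndarray:
        """All spike times pooled and sorted; optionally one polarity only."""
        chunks = []
        for t, p in zip(self.times, self.polarities):
            if polarity is None:
                chunks.append(t)
            else:
                chunks.append(t[p == polarity])
        if not chunks:
            return np.empty(0)
        return np.sort(np.concatenate(chunks))


def spike_shape(t, C: float = 1.0, tau: float = 1.0, kernel: str = "half-exp"):
    """The postsynaptic current waveform g(t); zero for t < 0.

    The first maximum of the default waveform sits at t* with
    tan(t*/tau) = 2, i.e. t* ~ 1.1071 tau.
    """
    t = np.asarray(t, dtype=float)
    if kernel == "half-exp":
        env = np.exp(-t / (2.0 * tau))
    elif kernel == "gaussian":
        env = np.exp(-(t**2) / tau)
    else:
        raise ConfigurationError("kernel must be 'half-exp' or 'gaussian'")
    out = C * np.sin(t / tau) * env
    return np.where(t >= 0.0, out, 0.0)


def _reverse_weights(ws: WeightSet) -> np.ndarray:
    """w_rev[j, k]: weight with which cell j's spike drives its k-th neighbor.

    Uses the symmetry of the offset scan: the reverse of offset rank k is
    rank M-1-k, so w_rev[j, k] = W[nbr[j, k], M-1-k].
    """
    nbr = ws.grid.neighbor_table
    M = ws.grid.M
    ranks = np.arange(M)
    return ws.W[nbr, M - 1 - ranks]


def simulate_async(ws: WeightSet, initial: np.ndarray, params: LIFParams) -> SpikeRaster:
    """Fixed-step LIF simulation of the spiking readout.

    The input frame is applied at t = 0 as simultaneous signed spikes (one
    per cell, polarity = pixel value).  Each cell then integrates
    du/dt = -u/tau_m + I(t), where I(t) sums the weighted, signed spike
    waveforms of its neighbors' past spikes; it fires a spike of polarity
    sgn(u) when |u| >= theta, resets to 0 and stays refractory.
    Deterministic: spike times are snapped to the integration grid.
    """
    grid = ws.grid
    initial = np.asarray(initial).reshape(-1)
    if initial.size != grid.N:
        raise ConfigurationError("initial frame does not match the grid")
    n_steps = int(round(params.T / params.dt))
    support = 12.0 * params.tau
    L = int(round(support / params.dt))
    gk = spike_shape(np.arange(L) * params.dt, params.C, params.tau, params.kernel)
    nbr = grid.neighbor_table
    w_rev = _reverse_weights(ws)

    drive = np.zeros((grid.N, n_steps + L))
    u = np.zeros(grid.N)
    ref_until = np.full(grid.N, -1.0)
    times: list[list[float]] = [[] for _ in range(grid.N)]
    pols: list[list[int]] = [[] for _ in range(grid.N)]

    def emit(cells: np.ndarray, polarity: np.ndarray, t: float, k: int) -> None:
        for j, s in zip(cells, polarity):
            drive[nbr[j], k : k + L] += (s * w_rev[j])[:, None] * gk
            times[j].append(t)
            pols[j].append(int(s))
        u[cells] = 0.0
        ref_until[cells] = t + params.refractory

    emit(np.arange(grid.N), np.sign(initial).astype(int), 0.0, 0)
    decay = 1.0 - params.dt / params.tau_m
    clock = params.clock_period
    next_tick = clock if clock is not None else np.inf
    for k in range(1, n_steps):
        t = k * params.dt
        u *= decay
        u += params.dt * drive[:, k]
        if clock is None:
            fired = np.flatnonzero((np.abs(u) >= params.theta) & (t >= ref_until))
            if fired.size:
                emit(fired, np.where(u[fired] >= 0.0, 1, -1), t, k)
        elif t >= next_tick:
            cells = np.arange(grid.N)
            emit(cells, np.where(u >= 0.0, 1, -1), t, k)
            next_tick += clock
    return SpikeRaster(
        times=[np.asarray(t) for t in times],
        polarities=[np.asarray(p, dtype=np.int8) for p in pols],
        T=params.T,
    )


def binarize_windows(
    raster: SpikeRaster, window: float, grid_shape: tuple[int, int]
) -> np.ndarray:
    """Frames from time windows tiling [0, T]: a cell is +1 in a window iff
    it emitted at least one positive spike inside it."""
    if window <= 0:
        raise ConfigurationError("window must be positive")
    H, W = grid_shape
    n_win = max(1, int(np.ceil(raster.T / window)))
    frames = -np.ones((n_win, H * W), dtype=np.int8)
    for cell, (ts, ps) in enumerate(zip(raster.times, raster.polarities)):
        pos = ts[ps > 0]
        if len(pos):
            idx = np.minimum((pos / window).astype(int), n_win - 1)
            frames[idx, cell] = 1
    return frames.reshape(n_win, H, W)


def spike_clusters(raster: SpikeRaster, gap: float) -> list[np.ndarray]:
    """Partition all spike times into clusters split at inter-spike gaps > gap.

    During faithful retrieval each cluster corresponds to one reproduced
    frame; the cluster width (standard deviation) measures the jitter.
    """
    ts = raster.all_times()
    if ts.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(ts) > gap) + 1
    return np.split(ts, cuts)


def cluster_widths(raster: SpikeRaster, gap: float) -> np.ndarray:
    return np.array([c.std() for c in spike_clusters(raster, gap)])


def cluster_frames(raster: SpikeRaster, gap: float, grid_shape: tuple[int, int]) -> np.ndarray:
    """One binary frame per detected spike cluster (positive spikes -> +1)."""
    H, W = grid_shape
    clusters = spike_clusters(raster, gap)
    frames = -np.ones((len(clusters), H * W), dtype=np.int8)
    pos_times = [t[p > 0] for t, p in zip(raster.times, raster.polarities)]
    for ci, c in enumerate(clusters):
        lo, hi = c.min(), c.max()
        for cell, ts in enumerate(pos_times):
            if len(ts) and np.any((ts >= lo) & (ts <= hi)):
                frames[ci, cell] = 1
    return frames.reshape(len(clusters), H, W)
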