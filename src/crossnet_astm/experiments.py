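"""Measurement protocols: capacity, fidelity, and noise-tolerance experiments.

Two fidelity regimes are used, following the phenomenology of the recording
rules.  Hebbian recording degrades gracefully: retrieval settles to a
stationary per-pixel error rate, so fidelity is the equilibrium pixel-error
probability, with the closed-form single-step theory

    p = (1/2) erfc( sqrt(M / 2Q) )

as the analytic reference.  Margin-trained rules (QP, AGD, DGD) fail
abruptly: retrieved movies are either near-perfect or completely corrupted,
so fidelity is the probability of whole-movie corruption estimated over an
ensemble of freshly generated random movies (one readout per movie, started
from a uniformly random frame).

Every stochastic experiment derives per-trial seeds from a single master
seed through ``numpy.random.SeedSequence.spawn`` and records its full
parameter snapshot, so results are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erfc, erfcinv

from .movie_io import Movie, flip_pixels, generate_movie
from .recording import RecorderParams, WeightSet, record, recording_succeeded
from .retrieval_sync import evaluate_recovery, retrieve, retrieve_loop, step_sync
from .topology import ConfigurationError, TorusGrid


# ---------------------------------------------------------------------------
# Analytic Hebb-rule theory


def hebb_error_probability(M: int, Q: int) -> float:
    """Single-step pixel-error probability of Hebbian recording.

    Assumes the previous frame is exactly correct; the M aligned terms of the
    local field compete with M(Q-1) independent +/-1 terms, giving a Gaussian
    signal-to-noise ratio sqrt(M/Q) and error probability
    (1/2) erfc(sqrt(M/(2Q))).
    """
    return float(0.5 * erfc(math.sqrt(M / (2.0 * Q))))


def hebb_error_asymptotic(M: int, Q: int) -> float:
    """Small-p asymptotic sqrt(Q/(2 pi M)) exp(-M/2Q), valid for 1 << Q << M."""
    return float(math.sqrt(Q / (2.0 * math.pi * M)) * math.exp(-M / (2.0 * Q)))


def hebb_capacity(p_target: float) -> float:
    """Normalized Hebb capacity Q_max/M at per-pixel error rate ``p_target``.

    Inverts the single-step formula: Q/M = 1 / (2 [erfcinv(2 p)]^2).
    At p_target = 0.01 this evaluates to 0.1848..., i.e. Q_max ~ 0.18 M.
    """
    if not 0.0 < p_target < 0.5:
        raise ConfigurationError("p_target must lie in (0, 1/2)")
    return float(1.0 / (2.0 * erfcinv(2.0 * p_target) ** 2))


# ---------------------------------------------------------------------------
# Result container


@dataclass(frozen=True)
class ExperimentResult:
    """A binomial probability estimate with its sampling error."""

    p: float
    trials: int
    params_snapshot: dict = field(default_factory=dict, compare=False)

    @property
    def standard_error(self) -> float:
        return math.sqrt(self.p * (1.0 - self.p) / self.trials)


def _spawn_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _movie_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


# ---------------------------------------------------------------------------
# Monte-Carlo measurements


def measure_single_step_error(ws: WeightSet, movie: Movie) -> float:
    """Pixel-error fraction of one synchronous step with the previous frame
    forced correct, pooled over all Q recorded transitions."""
    wrong = 0
    for q in range(movie.Q):
        pred = step_sync(ws, movie.frames[q])
        wrong += int((pred != movie.frames[(q + 1) % movie.Q]).sum())
    return wrong / (movie.Q * ws.grid.N)


def measure_pixel_error_rate(
    ws: WeightSet,
    movie: Movie,
    trials: int = 10,
    seed: int = 0,
    burn_in: int = 3,
) -> ExperimentResult:
    """Equilibrium per-pixel error rate of free-running retrieval.

    Runs full-loop retrievals from random recorded frames and averages the
    per-frame pixel-error fraction over the steps after ``burn_in`` (the
    error rate settles to its stationary value within a few frames).
    """
    Q = movie.Q
    if burn_in >= Q:
        raise ConfigurationError("burn_in must be smaller than Q")
    rngs = _spawn_rngs(seed, trials)
    errs = []
    pixels = 0
    for rng in rngs:
        q0 = int(rng.integers(Q))
        ref = np.stack([movie.frames[(q0 + k) % Q] for k in range(Q + 1)])
        trace = retrieve(ws, movie.frames[q0], Q, reference=ref)
        tail = trace.hamming[burn_in + 1 :]
        errs.append(tail.mean() / ws.grid.N)
        pixels += tail.size * ws.grid.N
    p = float(np.mean(errs))
    return ExperimentResult(
        p=p,
        trials=pixels,
        params_snapshot={"kind": "pixel_error_rate", "Q": Q, "trials": trials,
                         "burn_in": burn_in, "seed": seed},
    )


def measure_corruption_probability(
    grid: TorusGrid,
    recorder: RecorderParams,
    Q: int,
    trials: int,
    seed: int | np.random.SeedSequence = 0,
    d: float = 0.5,
) -> ExperimentResult:
    """Whole-movie corruption probability for a margin-trained rule.

    Each trial generates a fresh random movie, records it, runs one full
    closed-loop readout from a uniformly random start frame, and scores
    success by exact final-frame match.  A recording that fails its rule's
    own success criterion (non-convergence, infeasible cells) still gets its
    readout — failure is judged behaviorally — but is tallied in the
    snapshot separately.
    """
    rngs = _spawn_rngs(seed, trials)
    failures = 0
    recording_failures = 0
    for rng in rngs:
        movie = generate_movie(grid, Q, d, _movie_seed(rng))
        ws, report = record(movie, grid, recorder)
        if not recording_succeeded(report):
            recording_failures += 1
        q0 = int(rng.integers(Q))
        final = retrieve_loop(ws, movie.frames[q0], Q)
        ok, _ = evaluate_recovery(final, movie.frames[q0], tolerance=0.0)
        if not ok:
            failures += 1
    return ExperimentResult(
        p=failures / trials,
        trials=trials,
        params_snapshot={
            "kind": "corruption_probability", "rule": recorder.rule, "Q": Q,
            "d": d, "trials": trials, "recording_failures": recording_failures,
        },
    )


# ---------------------------------------------------------------------------
# Capacity estimation


def estimate_capacity(
    grid: TorusGrid,
    recorder: RecorderParams,
    p_target: float = 0.01,
    trials_per_Q: int = 50,
    seed: int = 0,
    d: float = 0.5,
    q_start: int | None = None,
    q_cap: int | None = None,
    coarse_step: int | None = None,
    refine_trials: int | None = None,
    resolution: int = 1,
) -> tuple[int, list[tuple[int, ExperimentResult]]]:
    """Estimate the memory capacity Q_max at corruption probability p_target.

    Scans Q upward in coarse steps (default ~0.1 M) until the estimated
    failure probability exceeds ``p_target``, then bisects between the last
    passing and first failing Q down to ``resolution`` frames (default one);
    ties break toward the smaller Q.  For the Hebb rule the criterion is the equilibrium
    per-pixel error rate instead of whole-movie corruption (graceful- vs
    abrupt-degradation regimes).

    Returns (Q_max, curve) where curve lists every (Q, ExperimentResult)
    evaluated, in evaluation order.
    """
    M = grid.M
    step = coarse_step or max(1, round(0.1 * M))
    q_lo = q_start or step
    q_hi_cap = q_cap or round(2.2 * M)
    refine_trials = refine_trials or trials_per_Q
    ss = np.random.SeedSequence(seed)
    curve: list[tuple[int, ExperimentResult]] = []

    def measure(Q: int, trials: int) -> ExperimentResult:
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(Q,))
        if recorder.rule == "hebb":
            res = _hebb_point(grid, Q, trials, child, d)
        else:
            res = measure_corruption_probability(grid, recorder, Q, trials, child, d)
        curve.append((Q, res))
        return res

    # Coarse ascent.
    q_pass, q_fail = None, None
    Q = q_lo
    while Q <= q_hi_cap:
        res = measure(Q, trials_per_Q)
        if res.p <= p_target:
            q_pass = Q
            Q += step
        else:
            q_fail = Q
            break
    if q_pass is None:
        return 0, curve
    if q_fail is None:
        return q_pass, curve  # never failed up to the cap

    # Bisection refinement.
    lo, hi = q_pass, q_fail
    while hi - lo > max(1, resolution):
        mid = (lo + hi) // 2
        res = measure(mid, refine_trials)
        if res.p <= p_target:
            lo = mid
        else:
            hi = mid
    return lo, curve


def _hebb_point(
    grid: TorusGrid, Q: int, trials: int, seed: np.random.SeedSequence, d: float
) -> ExperimentResult:
    """Equilibrium pixel-error rate at one (grid, Q), averaged over movies."""
    from .recording import record_hebb

    rngs = _spawn_rngs(seed, trials)
    rates = []
    for rng in rngs:
        movie = generate_movie(grid, Q, d, _movie_seed(rng))
        ws = record_hebb(movie, grid)
        res = measure_pixel_error_rate(ws, movie, trials=1, seed=_movie_seed(rng))
        rates.append(res.p)
    p = float(np.mean(rates))
    n_pix = trials * Q * grid.N
    return ExperimentResult(
        p=p, trials=n_pix,
        params_snapshot={"kind": "hebb_pixel_error", "Q": Q, "d": d, "trials": trials},
    )


# ---------------------------------------------------------------------------
# Noise experiments


def pixel_noise_experiment(
    grid: TorusGrid,
    recorder: RecorderParams,
    Q: int,
    f_values: Sequence[float],
    movies: int = 10,
    trials_per_movie: int = 100,
    seed: int = 0,
    d: float = 0.5,
) -> list[tuple[float, ExperimentResult]]:
    """Failure probability vs input-pixel corruption fraction f.

    Records ``movies`` independent movies once; for each f and each movie
    runs ``trials_per_movie`` readouts from a random start frame with exactly
    round(f N) flipped pixels, scoring success by exact final-frame match
    against the *uncorrupted* start frame.
    """
    rngs = _spawn_rngs(seed, movies)
    recorded = []
    for rng in rngs:
        movie = generate_movie(grid, Q, d, _movie_seed(rng))
        ws, _ = record(movie, grid, recorder)
        recorded.append((movie, ws, rng))
    out = []
    for f in f_values:
        failures = 0
        for movie, ws, rng in recorded:
            for _ in range(trials_per_movie):
                q0 = int(rng.integers(Q))
                start = flip_pixels(movie.frames[q0], f, _movie_seed(rng))
                final = retrieve_loop(ws, start, Q)
                ok, _ = evaluate_recovery(final, movie.frames[q0], tolerance=0.0)
                failures += not ok
        n = movies * trials_per_movie
        out.append((float(f), ExperimentResult(
            p=failures / n, trials=n,
            params_snapshot={"kind": "pixel_noise", "rule": recorder.rule,
                             "Q": Q, "f": float(f), "seed": seed},
        )))
    return out


def weight_noise_experiment(
    grid: TorusGrid,
    recorder: RecorderParams,
    Q: int,
    r_values: Sequence[float],
    success_tolerance: float = 0.01,
    movies: int = 10,
    trials_per_movie: int = 100,
    seed: int = 0,
    d: float = 0.5,
    stop_p: float | None = None,
    reference: str = "global",
) -> list[tuple[float, ExperimentResult]]:
    """Failure probability vs relative r.m.s. weight perturbation r.

    Before each readout attempt every weight is perturbed by independent
    zero-mean Gaussian noise of standard deviation r times the *global*
    r.m.s. of the recorded weight set (``reference='global'``, the default:
    per-weight relative noise would vanish on near-zero weights).  With
    ``reference='per-weight'`` the noise on each weight scales with that
    weight's own magnitude instead.  Success requires an error fraction at most
    ``success_tolerance`` in the final frame after one full loop from an
    uncorrupted random start frame.

    If ``stop_p`` is given and ``r_values`` is ascending, the sweep stops
    after two consecutive points whose failure probability exceeds it (the
    failure curve is monotone in r up to sampling noise, so further points
    carry no information about the tolerated level).
    """
    if reference not in ("global", "per-weight"):
        raise ConfigurationError("reference must be 'global' or 'per-weight'")
    rngs = _spawn_rngs(seed, movies)
    recorded = []
    for rng in rngs:
        movie = generate_movie(grid, Q, d, _movie_seed(rng))
        ws, _ = record(movie, grid, recorder)
        scale = ws.rms() if reference == "global" else np.abs(ws.W)
        recorded.append((movie, ws, scale, rng))
    out = []
    consecutive_high = 0
    for r in r_values:
        failures = 0
        for movie, ws, scale, rng in recorded:
            for _ in range(trials_per_movie):
                noisy = WeightSet(
                    grid=grid,
                    W=ws.W + r * scale * rng.standard_normal(ws.W.shape) if r > 0 else ws.W,
                )
                q0 = int(rng.integers(Q))
                final = retrieve_loop(noisy, movie.frames[q0], Q)
                ok, _ = evaluate_recovery(final, movie.frames[q0], success_tolerance)
                failures += not ok
        n = movies * trials_per_movie
        out.append((float(r), ExperimentResult(
            p=failures / n, trials=n,
            params_snapshot={"kind": "weight_noise", "rule": recorder.rule, "Q": Q,
                             "r": float(r), "tol": success_tolerance, "seed": seed},
        )))
        if stop_p is not None:
            consecutive_high = consecutive_high + 1 if out[-1][1].p > stop_p else 0
            if consecutive_high >= 2:
                break
    return out


def tolerated_noise(
    sweep: Iterable[tuple[float, ExperimentResult]], p_max: float = 0.01
) -> float:
    """Largest noise level whose failure probability (and that of every
    smaller level in the sweep) stays at or below ``p_max``."""
    best = 0.0
    for x, res in sweep:
        if res.p <= p_max:
            best = x
        else:
            break
    return best


def duty_cycle_scan(
    grid: TorusGrid,
    recorder: RecorderParams,
    d_values: Sequence[float],
    p_target: float = 0.01,
    trials_per_Q: int = 30,
    seed: int = 0,
    **capacity_kwargs,
) -> list[tuple[float, int]]:
    """Capacity Q_max as a function of the duty cycle d.

    The empirical full-scale law is Q_max proportional to 1/sqrt(d(1-d)):
    off-balance duty cycles reduce the effective pattern variance and raise
    capacity, symmetrically in d <-> 1-d.
    """
    out = []
    for k, d in enumerate(d_values):
        qmax, _ = estimate_capacity(
            grid, recorder, p_target=p_target, trials_per_Q=trials_per_Q,
            seed=seed + 1000 * k, d=float(d), **capacity_kwargs,
        )
        out.append((float(d), qmax))
    return out


def results_to_records(sweep: Iterable[tuple[float, ExperimentResult]]) -> list[dict]:
    """Flatten a sweep into tidy dict records (one per point) for CSV export."""
    recs = []
    for x, res in sweep:
        rec = {"x": x, "p": res.p, "stderr": res.standard_error, "trials": res.trials}
        rec.update(res.params_snapshot)
        recs.append(rec)
    return recs
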