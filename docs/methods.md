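# Methods

## Model

The package simulates an associative spatial-temporal memory: a network of
N binary neural cells arranged on an H x W lattice wrapped on a torus
(cyclic boundary conditions on both axes), each cell coupled to the
M = m^2 - 1 other cells inside the m x m square centred on it.  A "movie"
is a closed loop of Q frames; each frame assigns every cell a spin value
s in {-1, +1} ("active"/"inactive" pixel), drawn independently with
P(+1) = d (the duty cycle, 0.5 unless stated).  Recording chooses one
length-M synaptic weight vector w_i per cell so that the globally
synchronous readout

    I_i = sum_j w_ij V0 s_j      (local field over the M neighbors)
    s_i' = sgn(I_i),  sgn(0) := +1

maps every frame onto its successor; the closed loop contributes the
wrap-around pair (frame Q -> frame 1).  V0 only rescales analog levels and
never changes outcomes; the package fixes V0 = 1.

## Recording rules

* **Hebbian outer product** — w_ij = (1/Q) sum_q s_i^(q+1) s_j^(q).
  One-shot, local; weights are means of +/-1 terms, so |w_ij| <= 1 and
  Q w_ij is an integer of Q's parity.
* **Minimum-norm quadratic programming** — per cell, the smallest-norm
  vector satisfying the margin constraints s_i^(q+1) (w_i . s^(q)) >= kappa
  for all Q pairs.  The constraints and the norm separate over cells, so
  the joint problem decomposes exactly into N independent QPs.  A strict
  "> 0" constraint admits no attained minimum, so the package uses
  kappa = 1; any kappa > 0 rescales the weights without changing the sign
  readout.  The solver is a Hildreth-style cyclic coordinate ascent on the
  nonnegative dual (w_i = A_i' lambda_i, G = A A'), which maintains the
  achieved margins directly; a cell whose constraint set is infeasible
  (frame pairs not linearly separable at this connectivity) is flagged and
  keeps its best-effort weights.  Capacity scans may loosen the dual
  convergence tolerance — any feasible cell retrieves its recorded
  transitions identically — but noise studies keep the tight tolerance,
  because robustness to propagating errors does depend on where in the
  feasible polytope the solution lies.
* **Analog gradient descent (delta rule)** — per pair presentation,
  Delta w_ij = -eta s_j^(q) eps_i with eps_i = w_i . s^(q) - s_i^(q+1);
  eta = 0.001, zero-initialised weights, pairs presented in movie order
  with immediate updates (stochastic gradient descent, batch of one pair).
  Stops when all |eps| < 0.1 within an epoch, or at 1e5 epochs.  A tighter
  tolerance does not improve capacity; the rule wastes effort forcing the
  analog output onto the exact integer target when only the sign matters.
* **Discrete gradient descent with gap** — the error is ternary:
  eps_i = S_i - s_i^(q+1) with S_i = sgn(w_i . s^(q) - D s_i^(q+1)), so
  eps in {-2, 0, 2} and vanishes only once the field clears the gap,
  a_i s_i^(q+1) > D.  Updates as in the analog rule; D = 1; eta = 0.005
  for recording studies and 0.01 for the capacity measurement (both
  appear in the original study conditions; rescaling D before training
  provably rescales the whole weight trajectory proportionally, so D is an
  implementation convenience).  Convergence (a full epoch with zero
  updates) certifies exact one-step prediction of every recorded pair,
  hence exact replay of the whole loop.  The earlier "round to the nearest
  +/-1" variant without the gap is deliberately not shipped: it produces
  near-zero fields and poor noise immunity.

### Numerical choices

sgn(0) = +1 everywhere (deterministic tie-break; reachable from
zero-initialised training, measure-zero otherwise).  Gradient-descent
loops run in numba kernels.  The analog rule carries an extrapolative
early stop: its late-time error decay is geometric with a rate that only
slows as fast transients die out, so when a projection using the current
(optimistic) rate says the tolerance cannot be met within the epoch
budget, iteration is provably futile and the run is reported
non-convergent early.  The projection is checked every 500 epochs
starting at epoch 2000 and never fires on a run that would have
converged under the cap (the current-rate projection is a lower bound on
the epochs needed).

## Retrieval and scoring

Synchronous retrieval iterates the sign map; one full loop is Q steps.
A readout from a random recorded frame succeeds when the final frame
matches the start frame — exactly, for capacity and pixel-noise
experiments; up to a 1% (or 3%) pixel-error threshold for weight-noise
experiments, where the memory can replay the movie with a small persistent
error rate.  Margin-trained memories fail abruptly (a retrieved movie is
either near-perfect or fully corrupted), so their fidelity is the
whole-movie corruption probability over freshly generated random movies,
one readout per movie.  Hebbian memories degrade gracefully to a
stationary per-pixel error rate, measured after a three-frame burn-in;
their analytic single-step theory is

    p = (1/2) erfc( sqrt(M / 2Q) ),

the Gaussian tail of M aligned terms against M(Q-1) random ones, with the
small-p asymptotic sqrt(Q/2 pi M) exp(-M/2Q) and the inversion
Q_max/M = 1 / (2 [erfcinv(2p)]^2) = 0.1848 at p = 0.01.  Free-running
retrieval adds induced errors and sits above the single-step curve,
appreciably so only for p above the ~1% fidelity range.

Capacity Q_max is the largest Q whose failure probability stays at or
below 1%: a coarse ascent in steps of ~0.1 M brackets the boundary, then
bisection refines it to one-to-two frames, ties toward the smaller Q (the
failure curve is monotone in Q up to sampling noise).

## Asynchronous (spiking) readout

The leaky integrate-and-fire mode demonstrates the jitter phenomenology.
Every cell applies the input frame at t = 0 as one signed spike (positive
for active pixels, negative for inactive), matching the zero-centered
differential drive of the synchronous model; each spike injects
g(t) = C sin(t/tau) exp(-t/2tau) weighted by the synapse and signed by the
polarity into its neighbors.  A cell fires a spike of polarity sgn(u) when
|u| crosses theta, then resets and is refractory.  Defaults
(C = tau = 1, theta = 0.45, tau_m = 8, refractory = 2, dt = 0.02) are set
so that a unit local field fires a cell within about one spike duration;
none is critical.  The typeset form of the decay envelope is ambiguous
between exp(-t/2tau) and exp(-t^2/tau); the former is the default and the
latter a configuration option, and the demonstrated effects survive either
reading.  Below capacity, spikes cluster frame by frame; the cluster width
fluctuates but does not accumulate across the loop.  An optional global
clock (all cells emit sgn(u) at each tick) reduces the dynamics exactly to
the synchronous map — the package asserts this consistency in its tests.

## Noise experiments

Input noise flips exactly round(fN) distinct pixels of the start frame
(exact count, not Bernoulli, so sweeps are exact in f); success is exact
recovery of the uncorrupted start frame.  Weight noise adds independent
zero-mean Gaussians of standard deviation r x (global r.m.s. of the
recorded weights) to every weight before each attempt; the global
reference avoids the degeneracy of per-weight relative noise on near-zero
weights (a per-weight variant is available as an option).  The tolerated
level is the largest noise value whose failure probability — and that of
every smaller value scanned — stays at or below 1%, on an ascending grid
of step 0.02 with 10 movies x 100 attempts per point.

## The ternary-CAM baseline

A T-CAM stores each frame in one row, two binary devices per pixel, and
recognizes a corrupted input by the smallest Hamming distance.  Closed
forms: capacity n/2N frames for n devices (vs (7/8) n/N for the lattice
memory with differential synapses — a factor 7/4 advantage at equal device
count); misrecognition probability
(1/2){erf[(2f-1) sqrt(N/2)] - erf[-sqrt(N/2)]} (Gaussian approximation to
the Binomial(N, 1/2) wrong-row distance, with the exact binomial form as
the small-N oracle); and the worst-case variability margin
G_OFF,max < G_ON,max / 2.  The T-CAM tolerates input noise up to nearly
f = 1/2, far beyond the lattice memory, but stores 7/4 fewer frames per
device.

## What the synthetic generator does and does not emulate

Movies are fully random i.i.d. pixels at a given duty cycle — the
reference condition for all capacity numbers.  Real movies are spatially
and temporally correlated; correlation raises capacity (the duty-cycle
scan shows the trend: Q_max grows off the d = 0.5 symmetry point
approximately as 1/sqrt(d(1-d)), symmetric under d <-> 1-d), so the
random-movie capacities are conservative.  Passing tests therefore
certify the mechanics of recording and retrieval and the random-pattern
operating curves, not performance on structured footage.

## Problem sizes and finite-size effects

Desk-scale runs use lattices of N = 144-576 cells with M = 48-120
(the acceptance pipeline: M = 80 for the QP and discrete-GD capacity
scans, M = 48 for the analog-GD scan, M = 120 for weight-noise sweeps),
against the production scale N = 10,201, M = 440.  Two systematic
finite-size effects matter:

* **Capacity reduction.**  For the margin rules the failure boundary sits
  where N x P(one cell's Q dichotomies are not linearly separable) reaches
  the 1% criterion.  By the Cover count, that per-cell probability is a
  Gaussian tail in (2M - Q)/sqrt(Q), so the 1% boundary grows from about
  1.3-1.45 M at M = 48-80 toward about 1.7 M at M = 440, N = 10,201 —
  consistent with the full-scale 1.75 M (QP) and 1.67 M (discrete GD).
  Desk-scale normalized capacities are therefore expected to come out
  0.2-0.4 below the full-scale values; the analog rule, limited by the
  solvability of its analog equalities near Q = M rather than by the
  separability tail, scales much more mildly.
* **Noise-tolerance inflation.**  The tolerated weight noise is set by the
  smallest margin-to-norm ratio across all N cells and by the number of
  readout decisions N x Q; both shrink the tolerated r as the system
  grows.  Desk-scale tolerances come out higher than full scale —
  moderately for the minimum-norm QP (whose margin-to-norm ratio is a
  function of the fill alone), strongly for discrete GD, whose
  margin-to-norm quality degrades with the absolute length of the
  training trajectory.

The numbers printed by the acceptance pipeline are desk-scale
measurements under exactly the protocols above; the full-scale
input-noise operating point (M = 440, Q = 250, 500 flipped pixels,
corruption probability ~0.2) is provided as a separate long-running
script (`scripts/full_scale_pixel_noise.py`).

## Reproducibility

Every stochastic experiment takes one master seed; per-trial generators
derive from it via `numpy.random.SeedSequence.spawn`, and each result
carries its parameter snapshot.  Identical seeds reproduce bit-identical
movies, weights, and estimates on any platform (PCG64).

## Known limitations

Memristive device physics (conductance encoding, RC transients, in-situ
plasticity) is out of scope; the T-CAM comparison is closed-form only.
The linear-programming recording variant and sparse-pattern rules are
deliberately absent.  The mean-field treatment of induced Hebbian errors
is replaced by direct simulation.  The spiking module is a qualitative
demonstration, not a calibrated circuit model.
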