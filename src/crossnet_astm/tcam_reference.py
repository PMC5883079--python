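"""Closed-form reference model of a memristive ternary CAM (T-CAM).

The comparison baseline stores each frame in one row of a crossbar, two
binary-state devices per pixel; a corrupted input frame is recognized by the
row with the smallest Hamming distance (slowest match-line discharge).
Everything needed for the comparison reduces to closed forms: device-count
capacity, the Gaussian misrecognition probability, and the worst-case
ON/OFF-conductance margin criterion.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf
from scipy.stats import binom

from .topology import ConfigurationError


def tcam_capacity(n: float, N: float) -> float:
    """Frames storable in a T-CAM with n devices: Q_max = n / (2N)
    (two devices per stored pixel)."""
    if n <= 0 or N <= 0:
        raise ConfigurationError("n and N must be positive")
    return n / (2.0 * N)


def crossnet_capacity_devices(n: float, N: float) -> float:
    """Frames storable in a margin-trained lattice memory with n devices.

    With differential weight encoding (two devices per synapse) n = 2MN, and
    the best recording rules reach Q_max ~ 1.75 M at 1% fidelity, hence
    Q_max = (7/8) n / N — a factor 7/4 above the T-CAM at equal n.
    """
    if n <= 0 or N <= 0:
        raise ConfigurationError("n and N must be positive")
    return 0.875 * n / N


def tcam_error_probability(N: int, f: float) -> float:
    """Probability that a corrupted input matches a wrong stored frame.

    The Hamming distance between the input and an unrelated random frame is
    ~ Gaussian(N/2, N/4); an error requires it to fall below the distance fN
    to the correct frame.  Closed form:
    p = (1/2) { erf[(2f-1) sqrt(N/2)] - erf[-sqrt(N/2)] }.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError("f must lie in [0, 1]")
    a = math.sqrt(N / 2.0)
    return float(0.5 * (erf((2.0 * f - 1.0) * a) - erf(-a)))


def tcam_error_probability_exact(N: int, f: float) -> float:
    """Exact binomial variant of the misrecognition probability, for small N.

    The wrong-frame distance is Binomial(N, 1/2); the error event is
    distance <= floor(fN) (matching the Gaussian integral's range [0, fN]).
    Serves as the oracle for the Gaussian approximation.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError("f must lie in [0, 1]")
    return float(binom.cdf(math.floor(f * N), N, 0.5))


def tcam_error_probability_quadrature(N: int, f: float) -> float:
    """Direct numerical integration of the Gaussian misrecognition integral."""
    from scipy.integrate import quad

    sigma2 = N / 4.0
    val, _ = quad(
        lambda k: math.exp(-((k - N / 2.0) ** 2) / (2.0 * sigma2)), 0.0, f * N,
        epsabs=1e-14, epsrel=1e-13, limit=200,
    )
    return float(val / math.sqrt(2.0 * math.pi * sigma2))


def tcam_margin_ok(G_on_max: float, G_off_max: float) -> bool:
    """Worst-case device-variability criterion.

    The perfectly matching row still discharges through OFF-state leakage;
    misrecognition under worst-case conductance spreads requires
    G_OFF,max > G_ON,max / 2, so the margin holds iff G_OFF,max is strictly
    below half of G_ON,max.
    """
    if G_on_max <= 0 or G_off_max <= 0:
        raise ConfigurationError("conductances must be positive")
    return G_off_max < 0.5 * G_on_max


def comparison_table(N: int, M: int, f_values) -> list[dict]:
    """Side-by-side capacity and input-noise numbers at equal device count."""
    n = 2 * M * N
    rows = []
    for f in np.atleast_1d(f_values):
        rows.append({
            "f": float(f),
            "n_devices": n,
            "tcam_Qmax": tcam_capacity(n, N),
            "crossnet_Qmax": crossnet_capacity_devices(n, N),
            "tcam_error_p": tcam_error_probability(N, float(f)),
        })
    return rows
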