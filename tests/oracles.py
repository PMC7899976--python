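"""Dense, naive reference implementations used by the test suite.

Deliberately independent of the package internals: separate kernel code,
explicit matrix inverses, desk-scale problems only.
"""

from __future__ import annotations

import math

import numpy as np


def se_kernel(a: np.ndarray, b: np.ndarray, sigma_f: float, lengthscale: float) -> float:
    """Squared-exponential kernel with isotropic squared-lengthscale."""
    return sigma_f**2 * math.exp(-0.5 * float(np.sum((a - b) ** 2)) / lengthscale)


def batch_gp_posterior(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    sigma_f: float,
    lengthscale: float,
    noise_sd: float,
    jitter: float = 0.0,
):
    """Textbook GP regression posterior (mean, covariance) at the query points.

    train_X: (n, d) observed inputs; query_X: (q, d).  Uses explicit solves on
    densely assembled matrices.
    """
    n = len(train_X)
    q = len(query_X)
    Koo = np.array(
        [[se_kernel(train_X[i], train_X[j], sigma_f, lengthscale) for j in range(n)] for i in range(n)]
    )
    Kqo = np.array(
        [[se_kernel(query_X[i], train_X[j], sigma_f, lengthscale) for j in range(n)] for i in range(q)]
    )
    Kqq = np.array(
        [[se_kernel(query_X[i], query_X[j], sigma_f, lengthscale) for j in range(q)] for i in range(q)]
    )
    A = Koo + (noise_sd**2 + jitter) * np.eye(n)
    mean = Kqo @ np.linalg.solve(A, train_y)
    cov = Kqq - Kqo @ np.linalg.solve(A, Kqo.T)
    return mean, cov


def scalar_rgpr(
    x_loc: float,
    stream: list[tuple[float, float]],
    sigma_f: float,
    lengthscale: float,
    noise_sd: float,
):
    """Hand-rolled scalar (m=1, d=1) recursion over an (x_t, y_t) stream.

    Returns the per-step (predictive mean, predictive variance) list and the
    final (mean_f, cov_f) scalars.
    """
    k11 = sigma_f**2
    mu_f, c_f = 0.0, k11
    preds = []
    for x_t, y_t in stream:
        k_t1 = sigma_f**2 * math.exp(-0.5 * (x_t - x_loc) ** 2 / lengthscale)
        J = k_t1 / k11
        mu_p = J * mu_f
        c_p = sigma_f**2 - J * (k_t1 - c_f * J)
        G = c_f * J / (c_p + noise_sd**2)
        mu_f = mu_f + G * (y_t - mu_p)
        c_f = (1.0 - G * J) * c_f
        preds.append((mu_p, c_p))
    return preds, (mu_f, c_f)


def lag_step_response(P: float, tau_I: float, h: float, t: float) -> float:
    """Closed-form step response of the critically damped lag P/(tau_I s + 1)^2."""
    return P * h * (1.0 - math.exp(-t / tau_I) * (1.0 + t / tau_I))


def half_sine_pulse_width(duration: float, peak: float, amplitude: float) -> float:
    """Closed-form solve of (2 A t_a / pi)(T - t_a) = amplitude; smaller root."""
    disc = duration**2 - 2.0 * math.pi * amplitude / peak
    return 0.5 * (duration - math.sqrt(disc))
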