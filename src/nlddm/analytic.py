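"""Closed-form first-passage results for the constant-drift Wiener process.

These serve as an independent reference for the numerical Fokker–Planck
solver: the two-boundary first-passage densities come from the method of
images (reflection series), and the choice probability from the scale
function of the diffusion.  Nothing here shares code with the numeric
solver.

For ``dx = nu dt + sigma dW`` on ``(-B, B)`` started at ``y0`` (measured from
the lower boundary after rescaling to unit variance, interval length
``L = 2B/sigma``), the density of absorption at the lower boundary is

    g(t) = (2 pi t^3)^(-1/2) * sum_j (y0 + 2 j L)
           * exp( -v y0 - v^2 t / 2 - (y0 + 2 j L)^2 / (2 t) )

with ``v = nu / sigma``; the upper-boundary density follows by reflection
(``v -> -v``, ``y0 -> L - y0``).  Exponents are combined per term before
exponentiation so large drifts cannot overflow.
"""
from __future__ import annotations

import numpy as np

from .models import DdmParams

__all__ = ["wiener_fpt_density", "wiener_choice_probability"]

_N_IMAGES = 12  # reflection terms j in [-N, N]; ample for t <= ~10 s, B >= 0.2


def _lower_density(t: np.ndarray, v: float, y0: float, L: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    j = np.arange(-_N_IMAGES, _N_IMAGES + 1)
    x_j = y0 + 2.0 * j * L  # (n_images,)
    # combined exponent, shape (n_images, n_t)
    expo = -v * y0 - 0.5 * v * v * t[None, :] - (x_j[:, None] ** 2) / (2.0 * t[None, :])
    series = np.sum(x_j[:, None] * np.exp(expo), axis=0)
    g = series / np.sqrt(2.0 * np.pi * t**3)
    return np.maximum(g, 0.0)


def wiener_fpt_density(t, params: DdmParams, n_quad: int = 32):
    """Defective first-passage densities ``(f_correct, f_error)`` at times ``t``.

    ``t`` is decision time (the non-decision time is not applied here).  A
    uniform starting-point distribution (``sz > 0``) is handled by
    Gauss–Legendre quadrature over point starts.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("first-passage densities are defined for t > 0")
    L = 2.0 * params.B / params.sigma
    v = params.nu / params.sigma

    def point(y0):
        f_err = _lower_density(t, v, y0, L)
        f_cor = _lower_density(t, -v, L - y0, L)
        return f_cor, f_err

    if params.sz <= 0:
        y0 = (params.x0 + params.B) / params.sigma
        return point(y0)
    xs, ws = np.polynomial.legendre.leggauss(n_quad)
    f_cor = np.zeros_like(t)
    f_err = np.zeros_like(t)
    for xi, wi in zip(xs, ws):
        start = params.x0 + params.sz * xi
        c, e = point((start + params.B) / params.sigma)
        f_cor += 0.5 * wi * c
        f_err += 0.5 * wi * e
    return f_cor, f_err


def _p_upper_point(v: float, y0: float, L: float) -> float:
    # P(hit L before 0) from the scale function; v >= 0 branch is
    # overflow-safe, v < 0 follows by reflection.
    if abs(v) < 1e-12:
        return y0 / L
    if v < 0:
        return 1.0 - _p_upper_point(-v, L - y0, L)
    return float(np.expm1(-2.0 * v * y0) / np.expm1(-2.0 * v * L))


def wiener_choice_probability(params: DdmParams, n_quad: int = 64) -> float:
    """Probability of absorption at the correct (``+B``) boundary."""
    L = 2.0 * params.B / params.sigma
    v = params.nu / params.sigma
    if params.sz <= 0:
        return _p_upper_point(v, (params.x0 + params.B) / params.sigma, L)
    xs, ws = np.polynomial.legendre.leggauss(n_quad)
    starts = params.x0 + params.sz * xs
    return float(
        sum(0.5 * wi * _p_upper_point(v, (s + params.B) / params.sigma, L)
            for s, wi in zip(starts, ws))
    )
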