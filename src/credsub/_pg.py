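"""Pólya-Gamma PG(1, z) sampling.

Implements Devroye's alternating-series rejection sampler for the
Jacobi-type random variable J*(1, z), from which PG(1, psi) is obtained
as J*(1, |psi|/2) / 4.  The hot loop is compiled with numba; draws use
numba's internal RNG, seeded through :func:`seed` for reproducibility.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64
_SQRT2 = math.sqrt(2.0)

__all__ = ["seed", "draw", "draw_single", "mean", "variance"]


@njit(cache=True)
def _log_ndtr(a):
    # log of the standard normal CDF, stable for very negative a
    if a > -10.0:
        return math.log(0.5 * math.erfc(-a / _SQRT2))
    x = -a / _SQRT2
    # asymptotic erfc(x) ~ exp(-x^2)/(x sqrt(pi)) (1 - 1/(2 x^2))
    return (
        math.log(0.5)
        - x * x
        - math.log(x)
        - 0.5 * math.log(math.pi)
        + math.log1p(-0.5 / (x * x))
    )


@njit(cache=True)
def _invgauss_cdf(x, z):
    # CDF at x of the inverse Gaussian with mean 1/z, shape 1 (z >= 0)
    rx = 1.0 / math.sqrt(x)
    b = rx * (x * z - 1.0)
    a = -rx * (x * z + 1.0)
    return 0.5 * math.erfc(-b / _SQRT2) + math.exp(2.0 * z + _log_ndtr(a))


@njit(cache=True)
def _a_coef(n, x):
    # n-th term of the alternating series for the J*(1, 0) density
    npd = n + 0.5
    if x <= _TRUNC:
        return (
            math.pi
            * npd
            * math.pow(2.0 / (math.pi * x), 1.5)
            * math.exp(-2.0 * npd * npd / x)
        )
    return math.pi * npd * math.exp(-0.5 * npd * npd * math.pi * math.pi * x)


@njit(cache=True)
def _trunc_invgauss(z):
    # Inverse Gaussian (mean 1/z, shape 1) truncated to (0, _TRUNC]
    t = _TRUNC
    if z < 1.0 / t:
        # rejection from a truncated inverse-chi-square style proposal
        while True:
            while True:
                e1 = np.random.exponential()
                e2 = np.random.exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
                4.0 * mu * y + (mu * y) * (mu * y)
            )
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def draw_single(psi):
    """One draw from PG(1, psi)."""
    z = 0.5 * abs(psi)
    t = _TRUNC
    k = 0.125 * math.pi * math.pi + 0.5 * z * z
    # mixture weights of the two proposal pieces
    p = 0.5 * math.pi / k * math.exp(-k * t)
    q = 2.0 * math.exp(-z) * _invgauss_cdf(t, z)
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = t + np.random.exponential() / k  # right tail: shifted exponential
        else:
            x = _trunc_invgauss(z)  # left piece: truncated inverse Gaussian
        # series acceptance (squeeze): partial sums alternate around the density
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _draw_into(psi, out):
    for i in range(psi.shape[0]):
        out[i] = draw_single(psi[i])


@njit(cache=True)
def seed(value):
    """Seed the numba-internal RNG used by the PG sampler."""
    np.random.seed(value)


def draw(psi, out=None):
    """Draw PG(1, psi_i) for every element of ``psi``.

    Parameters
    ----------
    psi : ndarray
        Tilting parameters (any sign; the law depends on ``|psi|``).
    out : ndarray, optional
        Preallocated output of the same length.
    """
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    if out is None:
        out = np.empty_like(psi)
    _draw_into(psi, out)
    return out


def mean(psi):
    """Analytic mean of PG(1, psi): tanh(psi/2)/(2 psi), 1/4 at psi=0."""
    psi = np.asarray(psi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.tanh(psi / 2.0) / (2.0 * psi)
    return np.where(psi == 0.0, 0.25, m)


def variance(psi):
    """Analytic variance of PG(1, psi); 1/24 at psi=0."""
    psi = np.asarray(psi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (np.sinh(psi) - psi) / (4.0 * psi**3 * np.cosh(psi / 2.0) ** 2)
    return np.where(psi == 0.0, 1.0 / 24.0, v)
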