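"""Vectorized log-densities with analytic (z, sigma) gradients.

Hot path of the MCMC sampler: for each family, ``terms(y, z, sigma)`` returns
per-observation ``(logp, dlogp/dz, dlogp/dsigma)``.  The same parametrization
as :mod:`habmod.families` (whose scipy-backed ``logpdf`` is the reference these
functions are tested against); truncated-normal families include the
``Phi(mean/sigma)`` normalizer.  Overflowing inputs yield ``-inf`` log-density
(the sampler treats such points as divergent) rather than raising.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def _hazard(a):
    """phi(a) / Phi(a) for the standard normal, stable for very negative a."""
    return np.exp(-0.5 * a * a - _HALF_LOG_2PI - special.log_ndtr(a))


def _terms_N(y, z, sigma):
    u = (y - z) / sigma
    a = z / sigma
    h = _hazard(a)
    logp = -np.log(sigma) - _HALF_LOG_2PI - 0.5 * u * u - special.log_ndtr(a)
    dz = (u - h) / sigma
    ds = (u * u - 1.0 + h * a) / sigma
    return logp, dz, ds


def _terms_E(y, z, sigma):
    m = np.exp(np.minimum(z, 500.0))
    u = (y - m) / sigma
    a = m / sigma
    h = _hazard(a)
    logp = -np.log(sigma) - _HALF_LOG_2PI - 0.5 * u * u - special.log_ndtr(a)
    dm = (u - h) / sigma
    dz = m * dm
    ds = (u * u - 1.0 + h * a) / sigma
    return logp, dz, ds


def _terms_L(y, z, sigma):
    ly = np.log(y)
    r = (ly - z) / sigma
    logp = -ly - np.log(sigma) - _HALF_LOG_2PI - 0.5 * r * r
    dz = r / sigma
    ds = (r * r - 1.0) / sigma
    return logp, dz, ds


def _terms_G(y, z, sigma):
    ly = np.log(y)
    ratio = np.exp(np.minimum(ly - z, 500.0))  # y / exp(z)
    logp = -special.gammaln(sigma) - sigma * z + (sigma - 1.0) * ly - ratio
    dz = -sigma + ratio
    ds = -special.digamma(sigma) - z + ly
    return logp, dz, ds


def _terms_W(y, z, sigma):
    ly = np.log(y)
    w = sigma * (ly - z)
    ew = np.exp(np.minimum(w, 500.0))  # (y / exp(z))^sigma
    logp = np.log(sigma) + (sigma - 1.0) * ly - sigma * z - ew
    dz = sigma * (ew - 1.0)
    ds = 1.0 / sigma + (ly - z) * (1.0 - ew)
    return logp, dz, ds


_TERMS = {"N": _terms_N, "E": _terms_E, "L": _terms_L, "G": _terms_G, "W": _terms_W}


def terms(family: str, y, z, sigma):
    """Per-observation (logpdf, d/dz, d/dsigma) arrays for positive ``y``."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _TERMS[family](y, z, sigma)
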