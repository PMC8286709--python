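"""The five looking-time probability families.

Looking times are strictly positive durations (seconds).  Each family maps a
real *habituation state* ``z`` and a positive nuisance parameter ``sigma`` to a
distribution supported on the positive reals:

====  =======================================  ==========================
code  family                                   construction
====  =======================================  ==========================
N     truncated normal                         y ~ Normal(z, sigma) on (0, inf)
E     truncated normal with exponential mean   y ~ Normal(exp(z), sigma) on (0, inf)
L     lognormal                                log y ~ Normal(z, sigma)
W     Weibull                                  shape sigma, scale exp(z)
G     gamma                                    shape sigma, scale exp(z)
====  =======================================  ==========================

For N the state acts additively on the seconds scale; for the other four it
acts multiplicatively (E through the mean, L/W/G through the log scale, so
their geometric mean is linear in ``z``).  Multiplicative parameters are
conventionally reported as percent change via :func:`percent_change`.

Truncated-normal densities include the normalizer ``Phi(mean/sigma)`` so that
every family integrates to one on the positive half-line and log-likelihoods
are comparable across families.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "MULTIPLICATIVE_FAMILIES",
    "LOG_LINK_FAMILIES",
    "logpdf",
    "sample",
    "log_geometric_mean",
    "fisher_information",
    "parameter_correlation",
    "percent_change",
    "percent_to_shift",
]

FAMILIES = ("N", "E", "L", "W", "G")

#: families whose habituation state acts multiplicatively on looking time
MULTIPLICATIVE_FAMILIES = ("E", "L", "W", "G")

#: families whose geometric mean is a linear function of z (log previous LT is
#: the autoregressive carrier for these)
LOG_LINK_FAMILIES = ("L", "W", "G")

_EULER = np.euler_gamma


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown family code {family!r}; expected one of {FAMILIES}")
    return family


def _check_sigma(sigma) -> float:
    sigma = float(sigma)
    if not math.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive and finite, got {sigma}")
    return sigma


def _check_z(z) -> float:
    z = float(z)
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return z


def _frozen(family: str, z: float, sigma: float):
    """Frozen scipy distribution for a family at (z, sigma)."""
    if family == "N":
        return stats.truncnorm(a=-z / sigma, b=np.inf, loc=z, scale=sigma)
    if family == "E":
        m = math.exp(z)
        return stats.truncnorm(a=-m / sigma, b=np.inf, loc=m, scale=sigma)
    if family == "L":
        return stats.lognorm(s=sigma, scale=math.exp(z))
    if family == "W":
        return stats.weibull_min(c=sigma, scale=math.exp(z))
    if family == "G":
        return stats.gamma(a=sigma, scale=math.exp(z))
    raise AssertionError(family)


def logpdf(family: str, y, z, sigma):
    """Log-density of looking time ``y`` under a family at state ``(z, sigma)``.

    ``y`` may be a scalar or array of positive seconds.  Densities integrate to
    one on (0, inf); the truncation normalizer of N and E is included.
    """
    _check_family(family)
    z = _check_z(z)
    sigma = _check_sigma(sigma)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("looking times must be positive and finite")
    out = _frozen(family, z, sigma).logpdf(y)
    return float(out) if np.isscalar(y) or y.ndim == 0 else out


def sample(family: str, z, sigma, n: int, seed=None, rng=None):
    """Draw ``n`` looking times; reproducible given ``seed`` (or a Generator)."""
    _check_family(family)
    z = _check_z(z)
    sigma = _check_sigma(sigma)
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _frozen(family, z, sigma).rvs(size=n, random_state=rng)


def log_geometric_mean(family: str, z, sigma) -> float:
    """E[log Y]; equals ``z`` plus a sigma-only offset for the log-link families.

    N and E have no such linear form (their natural location summary is the
    truncated-normal mean) and raise ``ValueError``.
    """
    _check_family(family)
    z = _check_z(z)
    sigma = _check_sigma(sigma)
    if family == "L":
        return z
    if family == "G":
        return z + float(special.digamma(sigma))
    if family == "W":
        return z - _EULER / sigma
    raise ValueError(
        f"log geometric mean is not a linear summary for family {family!r}"
    )


def fisher_information(family: str, z, sigma) -> np.ndarray:
    """Expected per-observation Fisher information in the (z, sigma) parametrization.

    Closed forms; for N and E the information of the untruncated normal is used
    (the truncation correction is negligible when mean/sigma is large).  The
    result is symmetric positive definite.
    """
    _check_family(family)
    z = _check_z(z)
    sigma = _check_sigma(sigma)
    if family == "N":
        info = np.array([[1.0 / sigma**2, 0.0], [0.0, 2.0 / sigma**2]])
    elif family == "E":
        info = np.array(
            [[math.exp(2.0 * z) / sigma**2, 0.0], [0.0, 2.0 / sigma**2]]
        )
    elif family == "L":
        info = np.array([[1.0 / sigma**2, 0.0], [0.0, 2.0 / sigma**2]])
    elif family == "G":
        info = np.array([[sigma, 1.0], [1.0, float(special.polygamma(1, sigma))]])
    elif family == "W":
        c = 1.0 - _EULER
        info = np.array(
            [[sigma**2, -c], [-c, (math.pi**2 / 6.0 + c**2) / sigma**2]]
        )
    else:  # pragma: no cover
        raise AssertionError(family)
    # positive definiteness check (2x2: positive diagonal + positive determinant)
    if info[0, 0] <= 0 or np.linalg.det(info) <= 0:
        raise ArithmeticError(f"Fisher information not positive definite: {info}")
    return info


def parameter_correlation(family: str, sigma, signed: bool = False) -> float:
    """Asymptotic correlation between the two parameter estimates of a family.

    Computed from the inverse Fisher information.  By default the magnitude is
    returned (the convention used when tabulating orthogonality); with
    ``signed=True`` the off-diagonal sign of the inverse information is kept
    (negative for gamma, positive for Weibull, zero for N/E/L).

    Gamma obeys the closed form ``1 / sqrt(sigma * trigamma(sigma))`` and grows
    from 0 to 1 with sigma; Weibull is a constant (~0.31) independent of sigma.
    """
    _check_family(family)
    sigma = _check_sigma(sigma)
    if family in ("N", "E", "L"):
        return 0.0
    info = fisher_information(family, 0.0, sigma)
    cov = np.linalg.inv(info)
    r = cov[0, 1] / math.sqrt(cov[0, 0] * cov[1, 1])
    return float(r) if signed else float(abs(r))


def percent_change(z_delta, base: float = 0.0):
    """Multiplicative shift expressed as percent change: ``100*(exp(base + z) - 1)``."""
    z = np.asarray(z_delta, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z_delta must be finite")
    out = 100.0 * np.expm1(base + z)
    return float(out) if out.ndim == 0 else out


def percent_to_shift(percent, base: float = 0.0):
    """Inverse of :func:`percent_change`: ``log1p(percent/100) - base``."""
    p = np.asarray(percent, dtype=float)
    if np.any(p <= -100.0) or not np.all(np.isfinite(p)):
        raise ValueError("percent must be finite and greater than -100")
    out = np.log1p(p / 100.0) - base
    return float(out) if out.ndim == 0 else out
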