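"""Habituation-state time structures.

The habituation state z_{i,t} is the latent linear predictor that drives the
looking-time likelihood of infant i on trial t (1-based).  Three structures:

trend       z_t = alpha + beta*t + gamma*[t > d]
quadratic   z_t = alpha + beta*(t - delta)^2 + gamma*[t > d]   (delta shared)
ar          z_1 = alpha;  z_t = r(y_{t-1}) + beta + gamma*[t - 1 = d]

where d is the number of habituation trials, [.] the Iverson bracket, and the
autoregressive carrier r is the previous looking time itself for the truncated
normal family and its logarithm for every other family.  The dishabituation
term switches on strictly after trial d for trend/quadratic and fires exactly
on the first test trial for the autoregressive structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import families

__all__ = [
    "STRUCTURES",
    "StructureSpec",
    "state_trend",
    "state_quadratic",
    "state_ar",
    "states",
    "infant_loglik",
]

STRUCTURES = ("trend", "quadratic", "ar")

#: one-letter structure codes used in 3-letter model names (e.g. "GTP")
STRUCTURE_CODES = {"trend": "T", "quadratic": "Q", "ar": "A"}


@dataclass(frozen=True)
class StructureSpec:
    """Time-structure choice; ``shared_delta`` is meaningful only for quadratic."""

    code: str = "trend"
    shared_delta: float | None = None

    def __post_init__(self):
        if self.code not in STRUCTURES:
            raise ValueError(f"unknown structure {self.code!r}")
        if (self.shared_delta is not None) and self.code != "quadratic":
            raise ValueError("shared_delta is only valid for the quadratic structure")


def _check_trial(t, d):
    t = int(t)
    d = int(d)
    if t < 1 or d < 1:
        raise ValueError("trial index and habituation-trial count must be >= 1")
    return t, d


def state_trend(alpha, beta, gamma_, d, t):
    """alpha + beta*t + gamma*[t > d]."""
    t, d = _check_trial(t, d)
    return float(alpha + beta * t + gamma_ * (t > d))


def state_quadratic(alpha, beta, gamma_, delta, d, t):
    """alpha + beta*(t - delta)^2 + gamma*[t > d]; peak at t = delta when beta < 0."""
    t, d = _check_trial(t, d)
    return float(alpha + beta * (t - delta) ** 2 + gamma_ * (t > d))


def state_ar(alpha, beta, gamma_, d, t, prev_lt=None, family: str = "L"):
    """Autoregressive state: alpha at t = 1, else r(y_{t-1}) + beta + gamma*[t-1 = d]."""
    t, d = _check_trial(t, d)
    if t == 1:
        return float(alpha)
    if prev_lt is None or not np.isfinite(prev_lt) or prev_lt <= 0:
        raise ValueError("prev_lt (positive) is required for trial indices > 1")
    r = float(prev_lt) if family == "N" else float(np.log(prev_lt))
    return float(r + beta + gamma_ * (t - 1 == d))


def states(family, structure, trials, d, alpha, beta, gamma_, delta=None):
    """Vector of habituation states for one infant's ordered trials.

    ``structure`` may be a code string or a :class:`StructureSpec`; for the
    autoregressive structure the state on trial t uses the observed LT on
    trial t - 1.
    """
    if isinstance(structure, StructureSpec):
        if delta is None:
            delta = structure.shared_delta
        structure = structure.code
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    y = np.asarray(trials, dtype=float)
    if y.size == 0:
        raise ValueError("trials must be non-empty")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("looking times must be positive and finite")
    d = int(d)
    t = np.arange(1, y.size + 1)
    if structure == "trend":
        return alpha + beta * t + gamma_ * (t > d)
    if structure == "quadratic":
        if delta is None:
            raise ValueError("quadratic structure requires delta")
        return alpha + beta * (t - delta) ** 2 + gamma_ * (t > d)
    # autoregressive
    r = y[:-1] if family == "N" else np.log(y[:-1])
    z = np.empty(y.size)
    z[0] = alpha
    if y.size > 1:
        z[1:] = r + beta + gamma_ * (t[1:] - 1 == d)
    return z


def infant_loglik(family, structure, trials, d, alpha, beta, gamma_, sigma,
                  delta=None) -> float:
    """Log-likelihood of one infant's trial sequence under a family/structure.

    A pure function of a single infant's ordered looking times: the sum over
    trials of the family log-density evaluated at the structure's state.
    """
    z = states(family, structure, trials, d, alpha, beta, gamma_, delta=delta)
    y = np.asarray(trials, dtype=float)
    total = 0.0
    for yt, zt in zip(y, z):
        total += families.logpdf(family, yt, float(zt), sigma)
    return float(total)
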