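"""Posterior draws, sampler configuration, and convergence diagnostics.

Retained MCMC draws are stored per named variable as (chain, draw) arrays with
the split potential-scale-reduction statistic (R-hat) per variable; a fit is
flagged converged only when every variable satisfies R-hat < 1.1.  Posteriors
serialize to a long-format CSV (chain, iteration, variable, value) plus a JSON
diagnostics sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

__all__ = [
    "SamplerConfig",
    "STUDY_SAMPLER",
    "TEST_SAMPLER",
    "sampler_preset",
    "rhat",
    "Posterior",
    "posterior_summary",
    "RHAT_THRESHOLD",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run shape; retained draws = chains * (iterations - warmup) / thin."""

    chains: int = 6
    iterations: int = 10_000
    warmup: int = 6_000
    thin: int = 10
    seed: int | None = None
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self):
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("chains and thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return self.chains * ((self.iterations - self.warmup) // self.thin)

    def replace(self, **kw) -> "SamplerConfig":
        return dataclasses.replace(self, **kw)


#: the study's sampler configuration: 6 chains x 10,000 (6,000 warm-up), thin 10
STUDY_SAMPLER = SamplerConfig()

#: scaled-down default for routine work and tests
TEST_SAMPLER = SamplerConfig(chains=4, iterations=2_000, warmup=1_000, thin=1)

_PRESETS = {"study": STUDY_SAMPLER, "test": TEST_SAMPLER}


def sampler_preset(name: str) -> SamplerConfig:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown sampler preset {name!r}; expected 'study' or 'test'")


def rhat(draws) -> float:
    """Split potential-scale-reduction statistic of chain-tagged draws.

    ``draws`` is a (chains, draws-per-chain) array computed on retained
    (post-thinning) draws.  Approaches 1 as chains mix; NaN (with a warning)
    when the draws have zero total variance.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("rhat needs >= 2 chains with >= 4 draws each")
    if np.allclose(arr.var(), 0.0):
        warnings.warn("zero-variance draws: R-hat undefined, returning NaN", stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr, method="split"))


class Posterior:
    """Retained draws per variable with per-variable convergence statistics."""

    def __init__(self, draws: dict, config: SamplerConfig, spec: dict | None = None,
                 divergences: int = 0):
        self.draws = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
        self.config = config
        self.spec = dict(spec or {})
        self.divergences = int(divergences)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.rhat = {k: rhat(v) for k, v in self.draws.items()}
        finite = [v for v in self.rhat.values() if np.isfinite(v)]
        self.max_rhat = max(finite) if finite else float("nan")
        self.converged = bool(finite) and all(
            v < RHAT_THRESHOLD for v in finite
        )

    # -- access -----------------------------------------------------------
    @property
    def variables(self):
        return list(self.draws)

    @property
    def n_retained(self) -> int:
        first = next(iter(self.draws.values()))
        return int(first.size)

    def get(self, variable) -> np.ndarray:
        """Pooled draws of one variable (all chains concatenated)."""
        try:
            return self.draws[variable].reshape(-1)
        except KeyError:
            raise KeyError(f"unknown posterior variable {variable!r}") from None

    def median(self, variable) -> float:
        return float(np.median(self.get(variable)))

    def infant_medians(self) -> pd.DataFrame:
        """Per-infant marginal posterior medians of (alpha, beta, gamma, sigma)."""
        rows = {}
        for name in self.draws:
            if "[" not in name:
                continue
            base, iid = name.split("[", 1)
            iid = iid.rstrip("]")
            if base in ("alpha", "beta", "gamma", "sigma"):
                rows.setdefault(iid, {})[base] = self.median(name)
        out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("infant_id")
        return out.reset_index()

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, variable, value."""
        parts = []
        for name, arr in self.draws.items():
            n_chain, n_draw = arr.shape
            parts.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chain), n_draw),
                        "iteration": np.tile(np.arange(n_draw), n_chain),
                        "variable": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def save(self, path_prefix) -> None:
        """Write ``<prefix>.csv`` draws and ``<prefix>.json`` diagnostics."""
        self.to_frame().to_csv(f"{path_prefix}.csv", index=False)
        meta = {
            "spec": self.spec,
            "config": dataclasses.asdict(self.config),
            "rhat": {k: (None if not np.isfinite(v) else float(v))
                     for k, v in self.rhat.items()},
            "max_rhat": None if not np.isfinite(self.max_rhat) else float(self.max_rhat),
            "converged": self.converged,
            "divergences": self.divergences,
        }
        with open(f"{path_prefix}.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix) -> "Posterior":
        df = pd.read_csv(f"{path_prefix}.csv")
        with open(f"{path_prefix}.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        draws = {}
        for name, grp in df.groupby("variable", sort=False):
            piv = grp.pivot(index="chain", columns="iteration", values="value")
            draws[name] = piv.to_numpy()
        cfg = SamplerConfig(**meta["config"])
        return cls(draws, cfg, spec=meta.get("spec"),
                   divergences=meta.get("divergences", 0))

    def __repr__(self):
        return (
            f"<Posterior: {len(self.draws)} variables, {self.n_retained} draws, "
            f"max rhat {self.max_rhat:.3f}, converged={self.converged}>"
        )


def posterior_summary(posterior: Posterior, variable: str,
                      probs=(0.025, 0.25, 0.5, 0.75, 0.975)) -> dict:
    """Median and central intervals (50% and 95% by default) of one variable."""
    x = posterior.get(variable)
    qs = np.quantile(x, probs)
    out = {"median": float(np.quantile(x, 0.5)), "quantiles": dict(zip(probs, map(float, qs)))}
    if 0.25 in probs and 0.75 in probs:
        out["interval50"] = (out["quantiles"][0.25], out["quantiles"][0.75])
    if 0.025 in probs and 0.975 in probs:
        out["interval95"] = (out["quantiles"][0.025], out["quantiles"][0.975])
    return out
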