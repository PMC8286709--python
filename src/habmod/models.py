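"""Model specification and MCMC fitting.

A candidate model is a :class:`ModelSpec`: a probability family (N/E/L/W/G), a
time structure (trend/quadratic/ar), a pooling scheme (none/partial) and, for
the dishabituation parameter, either additive main effects (contrast + cohort +
habituation count) or a contrast x count interaction layout.  Models are named
by 3-letter codes — family, structure, pooling — e.g. ``GTP`` is the
gamma-trend partial-pooling model and ``NTN`` the truncated-normal trend
no-pooling model.

Fitting runs the package's No-U-Turn sampler over the joint posterior and
returns a :class:`~habmod.posterior.Posterior` whose convergence flag requires
split R-hat < 1.1 for every variable.  Non-converged fits are returned (and may
be saved) with the flag set false so callers can exclude them from comparison
reports.  The scikit-learn-style front door is :class:`HabituationModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _nuts
from ._joint import NoPoolModel, PartialPoolModel, Priors
from .data import LTDataset, assign_cohort
from .posterior import Posterior, SamplerConfig, sampler_preset
from .structures import STRUCTURE_CODES, STRUCTURES

__all__ = [
    "ModelSpec",
    "Priors",
    "HabituationModel",
    "fit_no_pooling",
    "fit_no_pooling_all",
    "fit_partial_pooling",
]

_STRUCTURE_FROM_CODE = {v: k for k, v in STRUCTURE_CODES.items()}
_POOLING_CODES = {"none": "N", "partial": "P"}
_POOLING_FROM_CODE = {v: k for k, v in _POOLING_CODES.items()}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: family x structure x pooling x gamma-effects layout."""

    family: str = "G"
    structure: str = "trend"
    pooling: str = "partial"
    gamma_effects: str = "main"

    def __post_init__(self):
        if self.family not in ("N", "E", "L", "W", "G"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.pooling not in ("none", "partial"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.gamma_effects not in ("main", "interaction"):
            raise ValueError(f"unknown gamma_effects {self.gamma_effects!r}")
        if self.gamma_effects == "interaction" and self.pooling != "partial":
            raise ValueError("the interaction layout requires partial pooling")

    @property
    def code(self) -> str:
        return self.family + STRUCTURE_CODES[self.structure] + _POOLING_CODES[self.pooling]

    @classmethod
    def from_code(cls, code: str, gamma_effects: str = "main") -> "ModelSpec":
        code = code.upper()
        if len(code) != 3:
            raise ValueError(f"model code must have 3 letters, got {code!r}")
        return cls(
            family=code[0],
            structure=_STRUCTURE_FROM_CODE[code[1]],
            pooling=_POOLING_FROM_CODE[code[2]],
            gamma_effects=gamma_effects,
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "structure": self.structure,
            "pooling": self.pooling,
            "gamma_effects": self.gamma_effects,
            "code": self.code,
        }


def _as_dataset(X) -> LTDataset:
    if isinstance(X, LTDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return LTDataset(X)
    raise TypeError("expected an LTDataset or a trial-level DataFrame")


def _run_sampler(model, config: SamplerConfig, spec_dict: dict) -> Posterior:
    """Run the configured chains over a joint model and assemble a Posterior."""
    ss = np.random.SeedSequence(config.seed)
    chain_draws = []
    divergences = 0
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        res = _nuts.sample_chain(
            model.logp_grad,
            model.initial_value(rng),
            n_iter=config.iterations,
            n_warmup=config.warmup,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
            metric_guess=model.metric_guess(),
        )
        chain_draws.append(res.draws[:: config.thin])
        divergences += res.divergences
    named = {}
    for draws in chain_draws:
        for name, series in model.constrain(draws).items():
            named.setdefault(name, []).append(series)
    stacked = {name: np.stack(parts) for name, parts in named.items()}
    return Posterior(stacked, config, spec=spec_dict, divergences=divergences)


def _resolve_config(sampler, seed=None) -> SamplerConfig:
    if isinstance(sampler, str):
        sampler = sampler_preset(sampler)
    if seed is not None and sampler.seed is None:
        sampler = sampler.replace(seed=seed)
    return sampler


def fit_partial_pooling(spec: ModelSpec, data, config: SamplerConfig | str = "test",
                        priors: Priors | None = None, drop_trial=None) -> Posterior:
    """Fit the hierarchical partial-pooling model to a whole dataset."""
    data = _as_dataset(data)
    config = _resolve_config(config)
    counts = data.infants().groupby(["contrast", "cohort"]).size()
    if (counts < 2).any():
        warnings.warn(
            "some contrast x cohort groups have a single infant; their group "
            "means are identified mostly by the prior", stacklevel=2,
        )
    model = PartialPoolModel(
        data, spec.family, spec.structure,
        gamma_effects=spec.gamma_effects, priors=priors, drop_trial=drop_trial,
    )
    return _run_sampler(model, config, spec.to_dict())


def fit_no_pooling_all(spec: ModelSpec, data, config: SamplerConfig | str = "test",
                       priors: Priors | None = None, drop_trial=None) -> Posterior:
    """No-pooling fits for every infant in a dataset, sampled jointly.

    The per-infant posteriors are mutually independent, so sampling the
    factorized joint posterior targets exactly the same distribution as
    fitting each infant separately.
    """
    data = _as_dataset(data)
    config = _resolve_config(config)
    model = NoPoolModel(
        data, spec.family, spec.structure, priors=priors, drop_trial=drop_trial
    )
    return _run_sampler(model, config, spec.to_dict())


def fit_no_pooling(spec: ModelSpec, trials, d: int,
                   config: SamplerConfig | str = "test",
                   priors: Priors | None = None,
                   infant_id: str = "i0001") -> Posterior:
    """Fit one infant's trials with the no-pooling model.

    ``trials`` are the ordered positive looking times; ``d`` the number of
    habituation trials.  The infant should contribute at least four trials
    (one more than the free mean-structure parameters).
    """
    y = np.asarray(trials, dtype=float)
    if y.size < 4:
        raise ValueError("no-pooling fits need at least 4 trials per infant")
    df = pd.DataFrame(
        {
            "infant_id": infant_id,
            "age_days": 200,
            "cohort": assign_cohort(200),
            "contrast": "luminance",
            "n_hab_trials": int(d),
            "trial": np.arange(1, y.size + 1),
            "lt_seconds": y,
        }
    )
    return fit_no_pooling_all(spec, LTDataset(df), config=config, priors=priors)


class HabituationModel(BaseEstimator):
    """Bayesian habituation looking-time model with a scikit-learn interface.

    Parameters mirror :class:`ModelSpec` plus the sampler configuration.
    ``fit(X)`` accepts an :class:`~habmod.data.LTDataset` or a trial-level
    DataFrame; fitted state lives in ``posterior_`` / ``converged_``.

    Examples
    --------
    >>> from habmod.data import GeneratorConfig, generate_dataset
    >>> data = generate_dataset(GeneratorConfig(), seed=1)
    >>> m = HabituationModel(family="G", structure="trend", pooling="partial")
    >>> m.fit(data)                                   # doctest: +SKIP
    """

    def __init__(self, family="G", structure="trend", pooling="partial",
                 gamma_effects="main", sampler="test", priors=None, seed=None):
        self.family = family
        self.structure = structure
        self.pooling = pooling
        self.gamma_effects = gamma_effects
        self.sampler = sampler
        self.priors = priors
        self.seed = seed

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.family, self.structure, self.pooling, self.gamma_effects)

    def fit(self, X, y=None, drop_trial=None):
        spec = self._spec()
        data = _as_dataset(X)
        config = _resolve_config(self.sampler, seed=self.seed)
        if spec.pooling == "partial":
            post = fit_partial_pooling(spec, data, config, priors=self.priors,
                                       drop_trial=drop_trial)
        else:
            post = fit_no_pooling_all(spec, data, config, priors=self.priors,
                                      drop_trial=drop_trial)
        self.model_code_ = spec.code
        self.posterior_ = post
        self.converged_ = post.converged
        self.data_ = data
        self.n_infants_ = data.n_infants
        return self

    def infant_medians(self) -> pd.DataFrame:
        """Per-infant posterior medians joined with condition labels."""
        self._check_fitted()
        med = self.posterior_.infant_medians()
        return med.merge(self.data_.infants(), on="infant_id")

    def score(self, X=None) -> float:
        """Total data log-likelihood at median parameter estimates."""
        from . import evaluation

        self._check_fitted()
        data = self.data_ if X is None else _as_dataset(X)
        return evaluation.loglik_at_medians(self._spec(), self.posterior_, data)

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise AttributeError("this HabituationModel instance is not fitted yet")
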