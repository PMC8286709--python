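"""Model-comparison metrics.

Three ways of scoring a fitted candidate model, all evaluated at per-variable
marginal posterior medians ("median parameter estimates"):

* data log-likelihood — plug the medians into the likelihood and sum;
* posterior-predictive mean absolute error — per trial, draw looking times
  from the model at the medians and average |draw - observed|, then average
  over trials within infant; reported as the across-infant distribution
  (median, 25-75 and 2.5-97.5 percentile bands) plus the grand mean;
* censored-trial prediction — refit with the fifth trial removed from the
  likelihood and score the held-out LT: its log-density at the medians and the
  absolute error of the posterior-predictive prediction at t = 5.

The censored experiment is defined for trend structures only; the
autoregressive state would need the censored trial itself as a predictor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import families, models, structures
from .data import LTDataset
from .posterior import Posterior, SamplerConfig

__all__ = [
    "FitReport",
    "loglik_at_medians",
    "mean_absolute_error",
    "censored_prediction",
    "comparison_table",
]


def _median_params(posterior: Posterior, data: LTDataset):
    med = posterior.infant_medians().set_index("infant_id")
    missing = [iid for iid, _, _, _ in data.iter_infants() if iid not in med.index]
    if missing:
        raise ValueError(f"posterior lacks infants {missing[:5]} present in the data")
    delta = posterior.median("delta") if "delta" in posterior.draws else None
    return med, delta


def loglik_at_medians(spec, posterior: Posterior, data) -> float:
    """Total data log-likelihood at per-infant median parameter estimates."""
    data = models._as_dataset(data)
    med, delta = _median_params(posterior, data)
    total = 0.0
    for iid, d, y, _ in data.iter_infants():
        p = med.loc[iid]
        total += structures.infant_loglik(
            spec.family, spec.structure, y, d,
            p["alpha"], p["beta"], p["gamma"], p["sigma"], delta=delta,
        )
    return float(total)


def mean_absolute_error(spec, posterior: Posterior, data, n_samples: int = 1000,
                        seed=None) -> dict:
    """Posterior-predictive mean absolute error in seconds.

    For every infant and trial, ``n_samples`` looking times are drawn from the
    model at the median parameters and the absolute error against the observed
    LT is averaged; trial errors are averaged within infant.
    """
    data = models._as_dataset(data)
    med, delta = _median_params(posterior, data)
    rng = np.random.default_rng(seed)
    per_infant = {}
    for iid, d, y, _ in data.iter_infants():
        p = med.loc[iid]
        z = structures.states(
            spec.family, spec.structure, y, d,
            p["alpha"], p["beta"], p["gamma"], delta=delta,
        )
        errs = []
        for yt, zt in zip(y, z):
            draws = families.sample(spec.family, float(zt), p["sigma"], n_samples, rng=rng)
            errs.append(float(np.mean(np.abs(draws - yt))))
        per_infant[iid] = float(np.mean(errs))
    vals = np.asarray(list(per_infant.values()))
    return {
        "per_infant": per_infant,
        "grand_mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "interval50": tuple(np.quantile(vals, [0.25, 0.75]).tolist()),
        "interval95": tuple(np.quantile(vals, [0.025, 0.975]).tolist()),
        "n_samples": int(n_samples),
    }


def censored_prediction(spec, data, config: SamplerConfig | str = "test",
                        priors=None, n_samples: int = 1000, seed=None,
                        censored_trial: int = 5) -> dict:
    """Hold out the fifth trial, refit, and score its prediction.

    Returns the held-out predictive log-likelihood, the absolute error of the
    mean posterior-predictive prediction, the draw-wise mean absolute error,
    and the refitted posterior.  Infants without a trial ``censored_trial``
    stay in the fit but are excluded from the metric.
    """
    if spec.structure != "trend":
        raise ValueError(
            "censored-trial prediction is defined for the trend structure only"
        )
    data = models._as_dataset(data)
    t5 = int(censored_trial)
    if not any(y.size >= t5 for _, _, y, _ in data.iter_infants()):
        raise ValueError(f"no infant has {t5} or more trials")
    if spec.pooling == "partial":
        post = models.fit_partial_pooling(spec, data, config, priors=priors,
                                          drop_trial=t5)
    else:
        post = models.fit_no_pooling_all(spec, data, config, priors=priors,
                                         drop_trial=t5)
    med, delta = _median_params(post, data)
    rng = np.random.default_rng(seed)
    loglik = 0.0
    err_mean_pred, err_drawwise = {}, {}
    for iid, d, y, _ in data.iter_infants():
        if y.size < t5:
            continue
        p = med.loc[iid]
        z5 = structures.state_trend(p["alpha"], p["beta"], p["gamma"], d, t5)
        y5 = float(y[t5 - 1])
        loglik += families.logpdf(spec.family, y5, z5, p["sigma"])
        draws = families.sample(spec.family, z5, p["sigma"], n_samples, rng=rng)
        err_mean_pred[iid] = abs(float(np.mean(draws)) - y5)
        err_drawwise[iid] = float(np.mean(np.abs(draws - y5)))
    mp = np.asarray(list(err_mean_pred.values()))
    dw = np.asarray(list(err_drawwise.values()))
    return {
        "model": spec.code,
        "censored_trial": t5,
        "n_scored": len(err_mean_pred),
        "pred_loglik": float(loglik),
        "abs_error_mean_prediction": {
            "per_infant": err_mean_pred,
            "grand_mean": float(np.mean(mp)),
            "median": float(np.median(mp)),
            "interval50": tuple(np.quantile(mp, [0.25, 0.75]).tolist()),
            "interval95": tuple(np.quantile(mp, [0.025, 0.975]).tolist()),
        },
        "abs_error_drawwise": {
            "per_infant": err_drawwise,
            "grand_mean": float(np.mean(dw)),
            "median": float(np.median(dw)),
        },
        "posterior": post,
        "converged": post.converged,
    }


@dataclass
class FitReport:
    """Evaluation results for one candidate model."""

    model: str
    converged: bool = True
    loglik: float | None = None
    mae: dict = field(default_factory=dict)
    pred_loglik: float | None = None
    pred_abs_error: float | None = None

    @classmethod
    def from_fit(cls, spec, posterior, data, n_samples=1000, seed=None) -> "FitReport":
        return cls(
            model=spec.code,
            converged=posterior.converged,
            loglik=loglik_at_medians(spec, posterior, data),
            mae=mean_absolute_error(spec, posterior, data, n_samples=n_samples,
                                    seed=seed),
        )

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        if "per_infant" in payload.get("mae", {}):
            payload["mae"] = {k: v for k, v in payload["mae"].items()
                              if k != "per_infant"}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def comparison_table(reports) -> "pd.DataFrame":
    """Across-model comparison (3-letter codes), non-converged models excluded."""
    import pandas as pd

    rows = []
    for rep in reports:
        if not rep.converged:
            continue
        rows.append(
            {
                "model": rep.model,
                "loglik": rep.loglik,
                "mae_grand_mean": rep.mae.get("grand_mean"),
                "mae_median": rep.mae.get("median"),
                "pred_loglik": rep.pred_loglik,
                "pred_abs_error": rep.pred_abs_error,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["model", "loglik", "mae_grand_mean", "mae_median",
                 "pred_loglik", "pred_abs_error"],
    )
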