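"""Tests for the model-comparison metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from habmod import ModelSpec, SamplerConfig
from habmod.data import LTDataset
from habmod.evaluation import (
    FitReport,
    censored_prediction,
    comparison_table,
    loglik_at_medians,
    mean_absolute_error,
)
from habmod.posterior import Posterior

TINY = SamplerConfig(chains=2, iterations=200, warmup=100, thin=1, seed=7)
FAST = SamplerConfig(chains=2, iterations=600, warmup=300, thin=1, seed=7)


def _frame(trials_by_infant, contrast="color"):
    rows = []
    for iid, (d, lts) in trials_by_infant.items():
        for t, lt in enumerate(lts, 1):
            rows.append((iid, 200, "7M", contrast, d, t, lt))
    return LTDataset(pd.DataFrame(rows, columns=[
        "infant_id", "age_days", "cohort", "contrast", "n_hab_trials",
        "trial", "lt_seconds"]))


def _degenerate_posterior(params_by_infant, extra=None):
    """Posterior whose every draw equals the given per-infant parameter values."""
    draws = {}
    for iid, p in params_by_infant.items():
        for name, val in p.items():
            draws[f"{name}[{iid}]"] = np.full((2, 10), float(val))
    for name, val in (extra or {}).items():
        draws[name] = np.full((2, 10), float(val))
    cfg = SamplerConfig(chains=2, iterations=20, warmup=10, thin=1)
    return Posterior(draws, cfg)


SPEC_N = ModelSpec("N", "trend", "none")
SPEC_G = ModelSpec("G", "trend", "none")


class TestLoglikAtMedians:
    def test_single_trial_hand_value(self):
        data = _frame({"a": (3, [3.0])})
        post = _degenerate_posterior(
            {"a": dict(alpha=3.0, beta=0.0, gamma=0.0, sigma=1.0)}
        )
        # truncated-normal density at its mode: phi(0) / Phi(3)
        expected = norm.logpdf(0.0) - norm.logcdf(3.0)
        assert loglik_at_medians(SPEC_N, post, data) == pytest.approx(expected)

    def test_each_infant_contributes_negatively(self):
        p = dict(alpha=3.0, beta=0.0, gamma=0.0, sigma=2.0)
        one = _frame({"a": (3, [3.0, 2.5])})
        two = _frame({"a": (3, [3.0, 2.5]), "b": (3, [4.0, 3.0])})
        post = _degenerate_posterior({"a": p, "b": p})
        assert loglik_at_medians(SPEC_N, post, two) < loglik_at_medians(
            SPEC_N, post, one
        )

    def test_depends_only_on_medians(self):
        data = _frame({"a": (3, [3.0, 2.5, 2.0, 1.8])})
        p = dict(alpha=1.0, beta=-0.05, gamma=0.1, sigma=1.5)
        degenerate = _degenerate_posterior({"a": p})
        # same medians, nonzero spread: identical value
        wobble = np.concatenate([-0.2 * np.ones(9), [0.0, 0.0], 0.2 * np.ones(9)])
        spread = Posterior(
            {f"{k}[a]": (v + wobble).reshape(2, 10) for k, v in p.items()},
            SamplerConfig(chains=2, iterations=20, warmup=10, thin=1),
        )
        assert loglik_at_medians(SPEC_G, spread, data) == pytest.approx(
            loglik_at_medians(SPEC_G, degenerate, data)
        )

    def test_missing_infant_rejected(self):
        data = _frame({"a": (3, [3.0]), "b": (3, [2.0])})
        post = _degenerate_posterior({"a": dict(alpha=1, beta=0, gamma=0, sigma=1)})
        with pytest.raises(ValueError, match="lacks infants"):
            loglik_at_medians(SPEC_N, post, data)


class TestMeanAbsoluteError:
    def test_degenerate_noise_limit(self):
        t = np.arange(1, 6)
        y = 4.0 - 0.3 * t
        data = _frame({"a": (5, list(y))})
        post = _degenerate_posterior(
            {"a": dict(alpha=4.0, beta=-0.3, gamma=0.0, sigma=0.01)}
        )
        out = mean_absolute_error(SPEC_N, post, data, n_samples=400, seed=1)
        assert out["grand_mean"] < 0.02

    def test_exponential_closed_form(self):
        # gamma with shape 1 at z = 0 is Exp(1); E|X - 1| = 2/e
        data = _frame({"a": (3, [1.0])})
        post = _degenerate_posterior(
            {"a": dict(alpha=0.0, beta=0.0, gamma=0.0, sigma=1.0)}
        )
        n = 4000
        out = mean_absolute_error(SPEC_G, post, data, n_samples=n, seed=3)
        se = 0.8 / np.sqrt(n)  # sd of |X-1| for Exp(1) is ~0.77
        assert abs(out["grand_mean"] - 2 / np.e) < 3 * se

    def test_seeded_determinism_and_order_invariance(self):
        y1, y2 = [4.0, 3.0, 2.5, 2.2], [5.0, 4.0, 3.0, 2.6]
        p = dict(alpha=1.2, beta=-0.05, gamma=0.0, sigma=2.0)
        ab = _frame({"a": (3, y1), "b": (3, y2)})
        ba = _frame({"b": (3, y2), "a": (3, y1)})
        post = _degenerate_posterior({"a": p, "b": p})
        r1 = mean_absolute_error(SPEC_G, post, ab, n_samples=300, seed=5)
        r2 = mean_absolute_error(SPEC_G, post, ab, n_samples=300, seed=5)
        r3 = mean_absolute_error(SPEC_G, post, ba, n_samples=300, seed=5)
        assert r1["grand_mean"] == r2["grand_mean"] == r3["grand_mean"]
        vals = list(r1["per_infant"].values())
        assert min(vals) <= r1["grand_mean"] <= max(vals)


class TestCensoredPrediction:
    def test_ar_structure_unsupported(self, tiny_dataset):
        with pytest.raises(ValueError, match="trend"):
            censored_prediction(ModelSpec("G", "ar", "none"), tiny_dataset)

    def test_censoring_removes_exactly_trial_five(self, tiny_dataset):
        from habmod._joint import _prepare_obs

        full = _prepare_obs(tiny_dataset, "G", "trend")
        cens = _prepare_obs(tiny_dataset, "G", "trend", drop_trial=5)
        n5 = int(np.sum(full["t"] == 5))
        assert n5 > 0
        assert len(cens["y"]) == len(full["y"]) - n5
        assert not np.any(cens["t"] == 5)

    def test_noiseless_data_predicts_heldout_trial(self):
        rng = np.random.default_rng(11)
        t = np.arange(1, 7)
        frame = {}
        for k in range(6):
            y = np.exp(1.3 - 0.07 * t + 0.2 * (t > 3)
                       + 0.02 * rng.normal(size=t.size))
            frame[f"i{k}"] = (3, list(y))
        data = _frame(frame)
        out = censored_prediction(ModelSpec("L", "trend", "none"), data,
                                  config=FAST, seed=2, n_samples=300)
        assert out["n_scored"] == 6
        assert out["abs_error_mean_prediction"]["grand_mean"] < 0.1

    def test_infants_without_fifth_trial_are_skipped_not_dropped(self):
        rng = np.random.default_rng(12)
        t6, t4 = np.arange(1, 7), np.arange(1, 5)
        frame = {
            "long0": (3, list(np.exp(1.2 - 0.07 * t6 + 0.05 * rng.normal(size=6)))),
            "long1": (3, list(np.exp(1.0 - 0.07 * t6 + 0.05 * rng.normal(size=6)))),
            "short": (1, list(np.exp(1.1 - 0.07 * t4 + 0.05 * rng.normal(size=4)))),
        }
        data = _frame(frame)
        out = censored_prediction(ModelSpec("L", "trend", "none"), data,
                                  config=TINY, seed=3, n_samples=100)
        assert out["n_scored"] == 2
        assert "short" not in out["abs_error_mean_prediction"]["per_infant"]
        # the short infant still has a posterior (it stayed in the fit)
        assert "alpha[short]" in out["posterior"].variables

    def test_same_seed_identical_metrics(self):
        rng = np.random.default_rng(13)
        t = np.arange(1, 7)
        frame = {f"i{k}": (3, list(np.exp(1.2 - 0.07 * t
                                          + 0.1 * rng.normal(size=6))))
                 for k in range(4)}
        data = _frame(frame)
        a = censored_prediction(ModelSpec("G", "trend", "none"), data,
                                config=TINY, seed=4, n_samples=100)
        b = censored_prediction(ModelSpec("G", "trend", "none"), data,
                                config=TINY, seed=4, n_samples=100)
        assert a["pred_loglik"] == b["pred_loglik"]
        assert (a["abs_error_mean_prediction"]["grand_mean"]
                == b["abs_error_mean_prediction"]["grand_mean"])


class TestFitReport:
    def test_report_and_comparison_table(self, tmp_path):
        data = _frame({"a": (3, [4.0, 3.5, 3.0, 2.8]), "b": (3, [5.0, 4.2, 3.8, 3.5])})
        p = dict(alpha=1.3, beta=-0.06, gamma=0.0, sigma=2.0)
        post = _degenerate_posterior({"a": p, "b": p})
        rep = FitReport.from_fit(SPEC_G, post, data, n_samples=200, seed=1)
        rep.converged = True  # synthetic degenerate posterior has undefined rhat
        rep.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").exists()
        table = comparison_table([rep])
        assert list(table["model"]) == ["GTN"]
        # non-converged models are excluded from the table
        rep2 = FitReport(model="NTN", converged=False, loglik=0.0)
        assert list(comparison_table([rep, rep2])["model"]) == ["GTN"]
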