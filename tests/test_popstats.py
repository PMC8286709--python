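"""Tests for the population-level analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habmod import popstats
from habmod.posterior import Posterior, SamplerConfig


def _medians_frame(alpha, contrast=None, cohort=None, hab=None, **extra):
    n = len(alpha)
    return pd.DataFrame(
        {
            "infant_id": [f"i{k}" for k in range(n)],
            "alpha": alpha,
            "contrast": contrast if contrast is not None else ["color"] * n,
            "cohort": cohort if cohort is not None else ["7M"] * n,
            "n_hab_trials": hab if hab is not None else [3] * n,
            **extra,
        }
    )


class TestAnova:
    def test_hand_computed_one_way_f(self):
        # groups {1,2,3} and {4,5,6}: F = 13.5 on (1, 4) df
        df = _medians_frame([1, 2, 3, 4, 5, 6],
                            contrast=["luminance"] * 3 + ["color"] * 3)
        out = popstats.anova_table(df, design={"alpha": ("S",)})
        row = out.iloc[0]
        assert row["F"] == pytest.approx(13.5)
        assert (row["df_num"], row["df_den"]) == (1, 4)
        assert row["significant"]

    def test_translation_invariance(self, rng):
        alpha = rng.normal(size=24)
        contrast = np.repeat(["luminance", "color"], 12)
        cohort = list(np.tile(np.repeat(["4M", "7M", "10M"], 4), 2))
        df1 = _medians_frame(alpha, contrast=contrast, cohort=cohort)
        df2 = _medians_frame(alpha + 100.0, contrast=contrast, cohort=cohort)
        design = {"alpha": ("S", "A", "S:A")}
        out1 = popstats.anova_table(df1, design=design)
        out2 = popstats.anova_table(df2, design=design)
        np.testing.assert_allclose(out1["F"], out2["F"], rtol=1e-8)

    def test_null_response_gives_f_near_one(self, rng):
        n = 300
        df = _medians_frame(
            rng.normal(size=n),
            contrast=list(rng.choice(["luminance", "color", "orientation"], n)),
            cohort=list(rng.choice(["4M", "7M", "10M"], n)),
        )
        out = popstats.anova_table(df, design={"alpha": ("S", "A", "S:A")})
        assert out["F"].mean() < 2.5
        assert not out["p"].min() < 1e-4

    def test_single_level_factor_dropped_with_warning(self, rng):
        df = _medians_frame(rng.normal(size=10),
                            contrast=["color"] * 10,
                            cohort=["4M"] * 5 + ["7M"] * 5)
        with pytest.warns(UserWarning, match="dropping term"):
            out = popstats.anova_table(df, design={"alpha": ("S", "A")})
        assert list(out["term"]) == ["A"]

    def test_zero_residual_variance_raises(self):
        df = _medians_frame([1.0, 1.0, 2.0, 2.0],
                            contrast=["luminance", "luminance", "color", "color"])
        with pytest.raises(ArithmeticError, match="residual variance"):
            popstats.anova_table(df, design={"alpha": ("S",)})

    def test_default_design_covers_gamma_interactions(self, rng):
        n = 48
        df = _medians_frame(
            rng.normal(size=n),
            contrast=list(np.tile(["luminance", "color"], n // 2)),
            cohort=list(np.tile(np.repeat(["4M", "7M", "10M"], 2), n // 6)),
            hab=list(np.tile(np.repeat([1, 3, 5, 7], 6), 2)),
            beta=rng.normal(size=n),
            gamma=rng.normal(size=n),
        )
        out = popstats.anova_table(df)
        gamma_terms = set(out.loc[out["parameter"] == "gamma", "term"])
        assert gamma_terms == {"S", "A", "S:A", "T", "T:S", "T:A", "T:S:A"}


class TestCorrelationTable:
    def _full(self, alpha, beta, gamma, sigma):
        df = _medians_frame(alpha)
        df["beta"], df["gamma"], df["sigma"] = beta, gamma, sigma
        return df

    def test_exact_linear_relation(self, rng):
        a = rng.normal(size=20)
        out = popstats.correlation_table(self._full(a, 2 * a + 1, rng.normal(size=20),
                                                    rng.gamma(2, 1, 20)))
        assert out["r_alpha_beta"] == pytest.approx(1.0)

    def test_sign_flip_negates_three_entries(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        g, s = rng.normal(size=30), rng.gamma(2, 1, 30)
        base = popstats.correlation_table(self._full(a, b, g, s))
        flipped = popstats.correlation_table(self._full(-a, b, g, s))
        for key in ("r_alpha_sigma", "r_alpha_beta", "r_alpha_gamma"):
            assert flipped[key] == pytest.approx(-base[key])
        assert flipped["r_beta_gamma"] == pytest.approx(base["r_beta_gamma"])

    def test_independent_parameters_stay_inside_fisher_band(self, rng):
        n = 300
        out = popstats.correlation_table(
            self._full(rng.normal(size=n), rng.normal(size=n),
                       rng.normal(size=n), rng.gamma(2, 1, n))
        )
        lo, hi = popstats.fisher_ci_halfwidth(n, 0.0)
        assert all(abs(v) < max(lo, hi) for v in out.values())

    def test_zero_variance_sentinel(self, rng):
        with pytest.warns(UserWarning, match="zero variance"):
            out = popstats.correlation_table(
                self._full(np.ones(10), rng.normal(size=10),
                           rng.normal(size=10), rng.gamma(2, 1, 10))
            )
        assert np.isnan(out["r_alpha_beta"])

    def test_minimum_sample(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            popstats.correlation_table(self._full([1.0], [1.0], [1.0], [1.0]))


def _group_posterior(values: dict):
    cfg = SamplerConfig(chains=2, iterations=20, warmup=10, thin=1)
    return Posterior({k: np.asarray(v, dtype=float).reshape(2, -1)
                      for k, v in values.items()}, cfg)


class TestMainEffects:
    def test_slope_displayed_as_minus_seven_percent(self):
        vals = np.full(20, np.log(0.93))
        post = _group_posterior({
            "mu_beta_contrast[luminance]": vals,
            "mu_beta_contrast[color]": vals,
            "mu_beta_cohort[4M]": np.zeros(20),
            "mu_alpha_contrast[luminance]": vals,
            "mu_alpha_cohort[4M]": np.zeros(20),
        })
        out = popstats.main_effects_summary(post, "G", parameters=("beta",))
        lum = out[(out["factor"] == "contrast") & (out["level"] == "luminance")]
        assert lum["median"].iloc[0] == pytest.approx(-7.0, abs=0.05)
        assert lum["unit"].iloc[0] == "percent"

    def test_truncated_normal_not_transformed(self):
        post = _group_posterior({
            "mu_beta_contrast[luminance]": np.full(20, -0.35),
            "mu_beta_cohort[4M]": np.zeros(20),
        })
        out = popstats.main_effects_summary(post, "N", parameters=("beta",))
        assert out["median"].iloc[0] == pytest.approx(-0.35)
        assert out["unit"].iloc[0] == "seconds/trial"

    def test_transform_commutes_with_quantiles(self, rng):
        draws = rng.normal(-0.05, 0.1, 20)
        post = _group_posterior({
            "mu_gamma_contrast[color]": draws,
            "mu_gamma_cohort[7M]": np.zeros(20),
        })
        out = popstats.main_effects_summary(post, "L", parameters=("gamma",))
        row = out[out["level"] == "color"].iloc[0]
        # the percent transform is monotone, so quantiles commute with it (up
        # to quantile interpolation between order statistics)
        assert row["median"] == pytest.approx(
            100 * (np.exp(np.median(draws)) - 1), rel=1e-3
        )

    def test_unknown_group_structure_raises(self):
        post = _group_posterior({"something_else": np.zeros(20)})
        with pytest.raises(KeyError):
            popstats.main_effects_summary(post, "G", parameters=("alpha",))


class TestDishabituationContrast:
    def _interaction_posterior(self, early, late, n=20):
        values = {}
        for b in ("luminance", "color"):
            for d, v in zip((1, 3, 5, 7), (early, early, late, late)):
                values[f"mu_gamma_cell[{b},{d}]"] = np.full(n, v)
        return _group_posterior(values)

    def test_null_contrast(self):
        out = popstats.dishabituation_contrast(self._interaction_posterior(0.3, 0.3))
        assert out["median_percent"] == pytest.approx(0.0, abs=1e-10)

    def test_point_two_contrast_is_22_percent(self):
        out = popstats.dishabituation_contrast(self._interaction_posterior(0.0, 0.2))
        assert out["median_percent"] == pytest.approx(100 * (np.exp(0.2) - 1), abs=1e-8)

    def test_antisymmetry_on_latent_scale(self):
        a = popstats.dishabituation_contrast(self._interaction_posterior(0.0, 0.2))
        b = popstats.dishabituation_contrast(self._interaction_posterior(0.2, 0.0))
        assert a["latent_median"] == pytest.approx(-b["latent_median"])

    def test_missing_cells_rejected(self):
        post = _group_posterior({"mu_gamma_cell[luminance,1]": np.zeros(20)})
        with pytest.raises(ValueError, match="interaction"):
            popstats.dishabituation_contrast(post)


def _scan_trials(p, c):
    t = 1
    while (1 - p) ** t > c:
        t += 1
    return t


class TestCriterionArithmetic:
    def test_seven_percent_reaches_half_in_ten_trials(self):
        assert popstats.trials_to_criterion(0.07, 0.5) == 10

    @pytest.mark.parametrize("p,c", [(0.5, 0.5), (0.07, 0.3), (0.2, 0.1)])
    def test_against_brute_force_scan(self, p, c):
        assert popstats.trials_to_criterion(p, c) == _scan_trials(p, c)

    @settings(max_examples=60, derandomize=True)
    @given(p=st.floats(0.01, 0.9), c=st.floats(0.05, 0.95))
    def test_monotonicity(self, p, c):
        # faster decay or a laxer criterion can only shorten habituation
        t = popstats.trials_to_criterion(p, c)
        assert popstats.trials_to_criterion(min(p + 0.05, 0.95), c) <= t
        assert popstats.trials_to_criterion(p, min(c + 0.04, 0.99)) <= t

    def test_domain(self):
        with pytest.raises(ValueError):
            popstats.trials_to_criterion(0.0, 0.5)
        with pytest.raises(ValueError):
            popstats.trials_to_criterion(0.07, 1.5)
        with pytest.raises(ValueError):
            popstats.trials_to_criterion(1.0, 0.5)


class TestRunningAverageCriterion:
    def test_seven_percent_needs_thirteen_trials(self):
        # independent brute force under LT_t = 0.93^(t-1)
        lt = lambda t: 0.93 ** (t - 1)
        base = np.mean([lt(t) for t in (1, 2, 3)])
        t = 3
        while np.mean([lt(s) for s in (t - 2, t - 1, t)]) > 0.5 * base:
            t += 1
        assert t == 13
        assert popstats.running_average_criterion_trials(0.07, 0.5, window=3) == 13

    def test_window_one_matches_plain_criterion_convention(self):
        # with a single-trial window the comparison is LT_t <= c * LT_1,
        # i.e. the plain criterion shifted by the t-1 decay convention
        assert popstats.running_average_criterion_trials(0.07, 0.5, window=1) == (
            popstats.trials_to_criterion(0.07, 0.5) + 1
        )

    def test_immediate_satisfaction(self):
        assert popstats.running_average_criterion_trials(0.07, 1.0, window=3) == 3


class TestFisherHalfwidth:
    def test_printed_value_at_n_301(self):
        lo, hi = popstats.fisher_ci_halfwidth(301, 0.0)
        assert lo == pytest.approx(0.113, abs=5e-4)
        assert hi == pytest.approx(lo)

    def test_direct_formula_at_n_103(self):
        lo, hi = popstats.fisher_ci_halfwidth(103, 0.0)
        assert hi == pytest.approx(np.tanh(1.959963985 / 10), abs=1e-6)

    def test_consistency_with_sample_size(self):
        lo, hi = popstats.fisher_ci_halfwidth(10**8, 0.3)
        assert lo < 1e-3 and hi < 1e-3

    def test_asymmetry_away_from_zero(self):
        lo, hi = popstats.fisher_ci_halfwidth(301, 0.6)
        assert hi < lo  # the interval is shorter toward +-1

    def test_domain(self):
        with pytest.raises(ValueError):
            popstats.fisher_ci_halfwidth(3, 0.0)
        with pytest.raises(ValueError):
            popstats.fisher_ci_halfwidth(100, 1.0)
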