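"""Population-level analyses of fitted habituation parameters.

Operates on per-infant posterior medians (no-pooling fits) or on group-level
posterior draws (partial pooling): omnibus ANOVA over the design factors,
pairwise parameter correlations, main-effect summaries with percent
transformation for multiplicative families, the early-vs-late dishabituation
contrast, and habituation-criterion / Fisher-interval arithmetic.

Design factors use the field's shorthand: S = stimulus contrast, A = age
cohort, T = number of habituation trials.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import families
from .posterior import Posterior

__all__ = [
    "DEFAULT_ANOVA_TERMS",
    "anova_table",
    "correlation_table",
    "main_effects_summary",
    "dishabituation_contrast",
    "trials_to_criterion",
    "running_average_criterion_trials",
    "fisher_ci_halfwidth",
]

_FACTOR_COLUMNS = {"S": "contrast", "A": "cohort", "T": "n_hab_trials"}
_FACTOR_ORDER = ("S", "A", "T")

#: factor terms tested per parameter (offset and slope: stimulus, age and their
#: interaction; dishabituation additionally the habituation-trial count)
DEFAULT_ANOVA_TERMS = {
    "alpha": ("S", "A", "S:A"),
    "beta": ("S", "A", "S:A"),
    "gamma": ("S", "A", "S:A", "T", "T:S", "T:A", "T:S:A"),
}


def _term_to_patsy(term: str) -> str:
    factors = sorted(term.split(":"), key=_FACTOR_ORDER.index)
    return ":".join(f"C({_FACTOR_COLUMNS[f]})" for f in factors)


def anova_table(medians: pd.DataFrame, design: dict | None = None,
                alpha_level: float = 0.05, typ: int = 2) -> pd.DataFrame:
    """Omnibus ANOVA (Type-II sums of squares) on per-infant parameter medians.

    ``medians`` needs the parameter columns named in ``design`` (default:
    alpha, beta, gamma) plus the factor columns contrast, cohort,
    n_hab_trials.  Factors reduced to a single observed level are dropped with
    a warning; a term is flagged significant at ``alpha_level``.
    """
    design = design or DEFAULT_ANOVA_TERMS
    rows = []
    for param, terms in design.items():
        df = medians.dropna(subset=[param]).copy()
        present = {
            f: df[_FACTOR_COLUMNS[f]].nunique() > 1
            for f in _FACTOR_ORDER
            if _FACTOR_COLUMNS[f] in df
        }
        usable = []
        for term in terms:
            factors = term.split(":")
            if all(present.get(f, False) for f in factors):
                usable.append(term)
            else:
                warnings.warn(
                    f"{param}: dropping term {term} (factor level missing)",
                    stacklevel=2,
                )
        if not usable:
            continue
        formula = f"{param} ~ " + " + ".join(_term_to_patsy(t) for t in usable)
        fit = smf.ols(formula, data=df).fit()
        if fit.df_resid < 1 or fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0):
            raise ArithmeticError(
                f"{param}: residual variance is zero, F statistics undefined"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(fit, typ=typ)
        df_den = int(table.loc["Residual", "df"])
        for term in usable:
            key = _term_to_patsy(term)
            rows.append(
                {
                    "parameter": param,
                    "term": term,
                    "F": float(table.loc[key, "F"]),
                    "df_num": int(table.loc[key, "df"]),
                    "df_den": df_den,
                    "p": float(table.loc[key, "PR(>F)"]),
                    "significant": bool(table.loc[key, "PR(>F)"] < alpha_level),
                }
            )
    return pd.DataFrame(rows)


_CORR_PAIRS = [
    ("alpha", "sigma"),
    ("beta", "sigma"),
    ("gamma", "sigma"),
    ("alpha", "beta"),
    ("alpha", "gamma"),
    ("beta", "gamma"),
]


def correlation_table(medians: pd.DataFrame) -> dict:
    """Pearson correlations between per-infant median parameter estimates.

    The six pairs among (alpha, beta, gamma, sigma); a zero-variance parameter
    yields NaN for its entries (with a warning).
    """
    if len(medians) < 4:
        raise ValueError("correlation table needs at least 4 infants")
    out = {}
    for a, b in _CORR_PAIRS:
        x = medians[a].to_numpy(dtype=float)
        y = medians[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero variance in {a if np.std(x) == 0 else b}; "
                          f"r_{a}_{b} undefined", stacklevel=2)
            out[f"r_{a}_{b}"] = float("nan")
        else:
            out[f"r_{a}_{b}"] = float(np.corrcoef(x, y)[0, 1])
    return out


_PARAM_PREFIX = {"alpha": "mu_alpha", "beta": "mu_beta", "gamma": "mu_gamma"}
_FACTOR_SUFFIX = {"contrast": "contrast", "cohort": "cohort", "hab": "hab"}


def _group_vars(posterior, prefix, factor):
    pre = f"{prefix}_{factor}["
    return [v for v in posterior.variables if v.startswith(pre)]


def main_effects_summary(posterior: Posterior, family: str,
                         parameters=("alpha", "beta", "gamma")) -> pd.DataFrame:
    """Displayed main effects of the partial-pooling fit, with intervals.

    For a level g of one factor the displayed quantity is the identified sum
    entering an infant's prior mean: the level's own group mean plus the
    average of the other factors' group means, computed draw-wise.  For
    multiplicative families the slope and dishabituation are transformed
    draw-wise to percent change; the truncated-normal family stays in seconds
    and offsets of multiplicative models stay in log-seconds.
    """
    multiplicative = family in families.MULTIPLICATIVE_FAMILIES
    rows = []
    for param in parameters:
        prefix = _PARAM_PREFIX[param]
        factors = [f for f in ("contrast", "cohort", "hab")
                   if _group_vars(posterior, prefix, f)]
        if not factors:
            raise KeyError(f"posterior has no group-level variables for {param}")
        factor_draws = {
            f: {v: posterior.get(v) for v in _group_vars(posterior, prefix, f)}
            for f in factors
        }
        for f in factors:
            others = [o for o in factors if o != f]
            offset = 0.0
            for o in others:
                offset = offset + np.mean(list(factor_draws[o].values()), axis=0)
            for var, draws in factor_draws[f].items():
                level = var.split("[", 1)[1].rstrip("]")
                shown = draws + offset
                unit = "seconds" if family == "N" else "log-seconds"
                if multiplicative and param in ("beta", "gamma"):
                    shown = families.percent_change(shown)
                    unit = "percent"
                elif param in ("beta", "gamma") and family == "N":
                    unit = "seconds/trial" if param == "beta" else "seconds"
                q = np.quantile(shown, [0.025, 0.25, 0.5, 0.75, 0.975])
                rows.append(
                    {
                        "parameter": param,
                        "factor": f,
                        "level": level,
                        "unit": unit,
                        "median": q[2],
                        "q25": q[1],
                        "q75": q[3],
                        "q2.5": q[0],
                        "q97.5": q[4],
                    }
                )
    return pd.DataFrame(rows)


def dishabituation_contrast(posterior: Posterior) -> dict:
    """Early-vs-late test-trial contrast of dishabituation, in percent.

    Requires the interaction (contrast x habituation count) layout for the
    dishabituation parameter.  Averages, over the luminance and color groups,
    late (5 or 7 habituation trials) minus early (1 or 3) cell means; the
    contrast is formed per posterior draw on the latent scale and then
    percent-transformed.
    """
    def cell(b, d):
        name = f"mu_gamma_cell[{b},{d}]"
        if name not in posterior.draws:
            raise ValueError(
                f"posterior lacks {name}; dishabituation_contrast needs the "
                "interaction gamma layout with luminance and color cells"
            )
        return posterior.get(name)

    latent = (
        cell("luminance", 5) + cell("luminance", 7)
        - cell("luminance", 1) - cell("luminance", 3)
        + cell("color", 5) + cell("color", 7)
        - cell("color", 1) - cell("color", 3)
    ) / 4.0
    pct = families.percent_change(latent)
    q = np.quantile(pct, [0.025, 0.5, 0.975])
    return {
        "median_percent": float(q[1]),
        "interval95_percent": (float(q[0]), float(q[2])),
        "latent_median": float(np.median(latent)),
    }


def _check_unit_interval(name, value, allow_one=False):
    value = float(value)
    hi_ok = value <= 1.0 if allow_one else value < 1.0
    if not (0.0 < value and hi_ok):
        interval = "(0, 1]" if allow_one else "(0, 1)"
        raise ValueError(f"{name} must lie in {interval}, got {value}")
    return value


def trials_to_criterion(per_trial_decrease, criterion) -> int:
    """Trials needed to reach a habituation criterion under geometric decay.

    Smallest integer t with ``(1 - per_trial_decrease)**t <= criterion``; e.g.
    a 7% per-trial decrease needs 10 trials to halve looking time.
    """
    p = _check_unit_interval("per_trial_decrease", per_trial_decrease)
    c = _check_unit_interval("criterion", criterion, allow_one=True)
    for t in range(1, 100_000):
        if (1.0 - p) ** t <= c:
            return t
    raise ArithmeticError("criterion not reached within 100000 trials")


def running_average_criterion_trials(per_trial_decrease, criterion,
                                     window: int = 3) -> int:
    """Trials needed when the criterion compares running-average looking times.

    Deterministic multiplicative decay LT_t = (1 - p)^(t-1); the smallest t
    (at least ``window``) whose trailing-window mean over trials t-window+1..t
    is at most ``criterion`` times the mean over trials 1..window.
    """
    p = _check_unit_interval("per_trial_decrease", per_trial_decrease)
    c = _check_unit_interval("criterion", criterion, allow_one=True)
    w = int(window)
    if w < 1:
        raise ValueError("window must be >= 1")
    lt = lambda t: (1.0 - p) ** (t - 1)
    base = np.mean([lt(t) for t in range(1, w + 1)])
    for t in range(w, 100_000):
        trail = np.mean([lt(s) for s in range(t - w + 1, t + 1)])
        if trail <= c * base:
            return t
    raise ArithmeticError("criterion not reached within 100000 trials")


def fisher_ci_halfwidth(n: int, r: float, level: float = 0.95):
    """Half-widths of the Fisher-z confidence interval for a correlation.

    Returns ``(lower, upper)`` non-negative half-widths of the normal-based
    interval ``tanh(atanh(r) +- z* / sqrt(n - 3))``; symmetric at r = 0 (about
    +-0.11 for n ~ 300) and shrinking as n grows.
    """
    n = int(n)
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    r = float(r)
    if not (-1.0 < r < 1.0):
        raise ValueError("r must lie strictly in (-1, 1)")
    from scipy import stats as _st

    zcrit = float(_st.norm.ppf(0.5 + level / 2.0))
    h = zcrit / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return (r - float(np.tanh(zr - h)), float(np.tanh(zr + h)) - r)
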