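"""Looking-time datasets: container, synthetic generator, exclusion rule, I/O.

A dataset is one row per infant per trial with columns ``infant_id, age_days,
cohort, contrast, n_hab_trials, trial, lt_seconds``.  The synthetic generator
emulates the habituation experiment's factorial design: 3 stimulus-contrast
conditions (luminance, color, orientation) x 3 age cohorts (4M, 7M, 10M) x 4
habituation-trial counts (1, 3, 5, 7) with unbalanced cell sizes, per-infant
parameters drawn from group-level normals, and a per-trial dropout hazard that
feeds the "< 3 test trials" exclusion rule.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import families, structures

__all__ = [
    "COHORTS",
    "CONTRASTS",
    "HAB_TRIAL_LEVELS",
    "STUDY_CELL_SIZES",
    "LTDataset",
    "GeneratorConfig",
    "assign_cohort",
    "generate_dataset",
    "apply_exclusion",
    "read_dataset",
    "write_dataset",
]

COHORTS = ("4M", "7M", "10M")
CONTRASTS = ("luminance", "color", "orientation")
HAB_TRIAL_LEVELS = (1, 3, 5, 7)

COLUMNS = [
    "infant_id",
    "age_days",
    "cohort",
    "contrast",
    "n_hab_trials",
    "trial",
    "lt_seconds",
]

# age boundaries in days; half-open on the younger cohort's upper edge so that
# 165 and 255 belong to the older cohort
_COHORT_EDGES = {"4M": (117, 165), "7M": (165, 255), "10M": (255, 340)}

#: sample sizes of the habituation study by (cohort, contrast, n_hab_trials)
STUDY_CELL_SIZES = {
    ("4M", "luminance", 1): 11, ("4M", "luminance", 3): 14,
    ("4M", "luminance", 5): 9, ("4M", "luminance", 7): 7,
    ("7M", "luminance", 1): 11, ("7M", "luminance", 3): 11,
    ("7M", "luminance", 5): 10, ("7M", "luminance", 7): 2,
    ("10M", "luminance", 1): 10, ("10M", "luminance", 3): 10,
    ("10M", "luminance", 5): 10, ("10M", "luminance", 7): 9,
    ("4M", "color", 1): 5, ("4M", "color", 3): 8,
    ("4M", "color", 5): 8, ("4M", "color", 7): 6,
    ("7M", "color", 1): 13, ("7M", "color", 3): 11,
    ("7M", "color", 5): 10, ("7M", "color", 7): 10,
    ("10M", "color", 1): 11, ("10M", "color", 3): 10,
    ("10M", "color", 5): 10, ("10M", "color", 7): 11,
    ("4M", "orientation", 1): 1, ("4M", "orientation", 3): 7,
    ("4M", "orientation", 5): 1, ("4M", "orientation", 7): 1,
    ("7M", "orientation", 1): 10, ("7M", "orientation", 3): 12,
    ("7M", "orientation", 5): 9, ("7M", "orientation", 7): 6,
    ("10M", "orientation", 1): 6, ("10M", "orientation", 3): 10,
    ("10M", "orientation", 5): 6, ("10M", "orientation", 7): 5,
}


def assign_cohort(age_days: int) -> str:
    """Age cohort for an age in days: [117, 165) -> 4M, [165, 255) -> 7M, [255, 339] -> 10M."""
    age = int(age_days)
    if age_days != age:
        raise ValueError("age_days must be an integer number of days")
    if 117 <= age < 165:
        return "4M"
    if 165 <= age < 255:
        return "7M"
    if 255 <= age <= 339:
        return "10M"
    raise ValueError(f"age {age} days is outside the study range [117, 339]")


class LTDataset:
    """Trial-level looking times with condition labels, one row per trial.

    Wraps a validated :class:`pandas.DataFrame` (``.df``) sorted by infant then
    trial.  ``meta`` optionally carries generator provenance (seed, config).
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None, validate: bool = True):
        df = df.loc[:, COLUMNS].copy()
        df = df.sort_values(["infant_id", "trial"], kind="stable").reset_index(drop=True)
        if validate:
            _validate_frame(df)
        self.df = df
        self.meta = dict(meta or {})

    # -- basic access -----------------------------------------------------
    @property
    def n_infants(self) -> int:
        return self.df["infant_id"].nunique()

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def infants(self) -> pd.DataFrame:
        """One row per infant: labels plus total trial count."""
        g = self.df.groupby("infant_id", sort=True)
        out = g.agg(
            age_days=("age_days", "first"),
            cohort=("cohort", "first"),
            contrast=("contrast", "first"),
            n_hab_trials=("n_hab_trials", "first"),
            n_trials=("trial", "max"),
        ).reset_index()
        return out

    def iter_infants(self):
        """Yield (infant_id, d, looking-time array ordered by trial, row of labels)."""
        for iid, grp in self.df.groupby("infant_id", sort=True):
            d = int(grp["n_hab_trials"].iloc[0])
            yield iid, d, grp["lt_seconds"].to_numpy(), grp.iloc[0]

    def subset(self, infant_ids) -> "LTDataset":
        keep = self.df["infant_id"].isin(set(infant_ids))
        return LTDataset(self.df.loc[keep], meta=self.meta, validate=False)

    def __eq__(self, other):
        return isinstance(other, LTDataset) and self.df.equals(other.df)

    def __repr__(self):
        return f"<LTDataset: {self.n_infants} infants, {self.n_trials} trials>"


def _validate_frame(df: pd.DataFrame) -> None:
    lt = df["lt_seconds"].to_numpy(dtype=float)
    bad = ~np.isfinite(lt) | (lt <= 0)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"non-positive or non-finite looking time in row {row} "
            f"(infant {df.loc[row, 'infant_id']}, trial {df.loc[row, 'trial']})"
        )
    for iid, grp in df.groupby("infant_id", sort=False):
        t = grp["trial"].to_numpy(dtype=int)
        if not np.array_equal(t, np.arange(1, t.size + 1)):
            raise ValueError(f"infant {iid}: trial indices must run 1..T consecutively")
        for col in ("age_days", "cohort", "contrast", "n_hab_trials"):
            if grp[col].nunique() != 1:
                raise ValueError(f"infant {iid}: column {col} is not constant")
        expected = assign_cohort(int(grp["age_days"].iloc[0]))
        if str(grp["cohort"].iloc[0]) != expected:
            raise ValueError(
                f"infant {iid}: cohort {grp['cohort'].iloc[0]!r} inconsistent with "
                f"age {int(grp['age_days'].iloc[0])} days (expected {expected!r})"
            )
        if str(grp["contrast"].iloc[0]) not in CONTRASTS:
            raise ValueError(f"infant {iid}: unknown contrast {grp['contrast'].iloc[0]!r}")
        if int(grp["n_hab_trials"].iloc[0]) not in HAB_TRIAL_LEVELS:
            warnings.warn(
                f"infant {iid}: n_hab_trials {int(grp['n_hab_trials'].iloc[0])} is "
                f"outside the study levels {HAB_TRIAL_LEVELS}",
                stacklevel=3,
            )


@dataclass
class GeneratorConfig:
    """Synthetic-generator settings; defaults are the study's conditions.

    Group-level means follow the partial-pooling hierarchy: an infant in
    (contrast b, cohort c, habituation count d) draws
    ``alpha ~ N(alpha_contrast[b] + alpha_cohort[c], scale_alpha)`` and
    likewise for beta; ``gamma ~ N(gamma_contrast[b] + gamma_cohort[c] +
    gamma_hab[d], scale_gamma)``.  Defaults (gamma-trend, log-seconds scale):
    per-trial decrease of 7% (ln 0.93) and trial-1 mean looking times of about
    3.7 s for luminance and 5 s for the other contrasts at shape ~2.1.
    Per-infant sigma is lognormal; dropout is a geometric per-trial hazard
    after trial 1 and sessions run at most d + n_test_trials trials.
    """

    family: str = "G"
    structure: str = "trend"
    cell_sizes: dict = field(default_factory=lambda: dict(STUDY_CELL_SIZES))
    alpha_contrast: dict = field(
        default_factory=lambda: {"luminance": 0.639, "color": 0.940, "orientation": 0.940}
    )
    alpha_cohort: dict = field(
        default_factory=lambda: {"4M": -0.10, "7M": 0.0, "10M": 0.10}
    )
    beta_contrast: dict = field(
        default_factory=lambda: {c: float(np.log(0.93)) for c in CONTRASTS}
    )
    beta_cohort: dict = field(default_factory=lambda: {k: 0.0 for k in COHORTS})
    gamma_contrast: dict = field(
        default_factory=lambda: {"luminance": 0.30, "color": 0.20, "orientation": -0.05}
    )
    gamma_cohort: dict = field(default_factory=lambda: {k: 0.0 for k in COHORTS})
    gamma_hab: dict = field(
        default_factory=lambda: {1: 0.0, 3: 0.0, 5: 0.10, 7: 0.10}
    )
    scale_alpha: float = 0.30
    scale_beta: float = 0.05
    scale_gamma: float = 0.15
    sigma_log_mean: float = float(np.log(2.1))
    sigma_log_sd: float = 0.20
    delta: float = 1.0  # quadratic peak trial (shared)
    dropout_hazard: float = 0.03
    n_test_trials: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.family not in families.FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.structure not in structures.STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        for n in self.cell_sizes.values():
            if int(n) < 0:
                raise ValueError("cell sizes must be non-negative")
        for s in (self.scale_alpha, self.scale_beta, self.scale_gamma, self.sigma_log_sd):
            if s < 0:
                raise ValueError("population scales must be non-negative")
        if not (0.0 <= self.dropout_hazard < 1.0):
            raise ValueError("dropout hazard must be in [0, 1)")

    @classmethod
    def for_family(cls, family: str, **overrides) -> "GeneratorConfig":
        """Study-condition defaults re-expressed on a family's native scale."""
        if family in ("N", "E"):
            # additive residual in seconds; keep trial-1 means at 3.7 s / 5 s
            if family == "N":
                kw = dict(
                    alpha_contrast={"luminance": 4.05, "color": 5.35, "orientation": 5.35},
                    alpha_cohort={"4M": -0.4, "7M": 0.0, "10M": 0.4},
                    beta_contrast={c: -0.35 for c in CONTRASTS},
                    gamma_contrast={"luminance": 0.6, "color": 0.4, "orientation": -0.1},
                    gamma_hab={1: 0.0, 3: 0.0, 5: 0.2, 7: 0.2},
                    scale_alpha=0.8,
                    scale_beta=0.08,
                    scale_gamma=0.3,
                    sigma_log_mean=float(np.log(1.2)),
                )
            else:
                kw = dict(
                    alpha_contrast={
                        "luminance": float(np.log(3.7) - np.log(0.93)),
                        "color": float(np.log(5.0) - np.log(0.93)),
                        "orientation": float(np.log(5.0) - np.log(0.93)),
                    },
                    sigma_log_mean=float(np.log(1.2)),
                )
        elif family in ("L", "W"):
            # log-scale state as for gamma; alpha targets the trial-1 mean
            kw = dict(
                alpha_contrast={
                    "luminance": float(np.log(3.7) - np.log(0.93)),
                    "color": float(np.log(5.0) - np.log(0.93)),
                    "orientation": float(np.log(5.0) - np.log(0.93)),
                },
                sigma_log_mean=float(np.log(0.5)) if family == "L" else float(np.log(1.6)),
            )
        else:
            kw = {}
        kw["family"] = family
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["cell_sizes"] = {
            f"{k[0]}|{k[1]}|{k[2]}": int(v) for k, v in self.cell_sizes.items()
        }
        out["gamma_hab"] = {str(k): v for k, v in self.gamma_hab.items()}
        return out


def generate_dataset(config: GeneratorConfig | None = None, seed=None) -> LTDataset:
    """Generate a synthetic looking-time dataset under the configured hierarchy.

    For every infant of every design cell: draw (alpha, beta, gamma) from the
    group normals and sigma from its lognormal hyperdistribution, then draw the
    trial sequence from the configured family/structure.  A geometric dropout
    hazard may end the session early, which later triggers the exclusion rule.
    Byte-identical output for a fixed seed.
    """
    config = config or GeneratorConfig()
    if seed is None:
        seed = config.seed
    if sum(int(n) for n in config.cell_sizes.values()) == 0:
        raise ValueError("empty design: all cell sizes are zero")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for (cohort, contrast, d), n_cell in sorted(config.cell_sizes.items()):
        lo, hi = _COHORT_EDGES[cohort]
        for _ in range(int(n_cell)):
            counter += 1
            iid = f"i{counter:04d}"
            age = int(rng.integers(lo, hi))
            alpha = rng.normal(
                config.alpha_contrast[contrast] + config.alpha_cohort[cohort],
                config.scale_alpha,
            )
            beta = rng.normal(
                config.beta_contrast[contrast] + config.beta_cohort[cohort],
                config.scale_beta,
            )
            gamma_ = rng.normal(
                config.gamma_contrast[contrast]
                + config.gamma_cohort[cohort]
                + config.gamma_hab[d],
                config.scale_gamma,
            )
            sigma = float(
                np.exp(rng.normal(config.sigma_log_mean, config.sigma_log_sd))
            )
            max_trials = d + int(config.n_test_trials)
            y = []
            for t in range(1, max_trials + 1):
                if t > 1 and rng.random() < config.dropout_hazard:
                    break
                if config.structure == "trend":
                    z = structures.state_trend(alpha, beta, gamma_, d, t)
                elif config.structure == "quadratic":
                    z = structures.state_quadratic(
                        alpha, beta, gamma_, config.delta, d, t
                    )
                else:
                    prev = y[-1] if t > 1 else None
                    z = structures.state_ar(
                        alpha, beta, gamma_, d, t, prev_lt=prev, family=config.family
                    )
                yt = float(families.sample(config.family, z, sigma, 1, rng=rng)[0])
                y.append(yt)
                rows.append((iid, age, cohort, contrast, d, t, yt))
    df = pd.DataFrame(rows, columns=COLUMNS)
    meta = {"seed": None if seed is None else int(seed), "config": config.to_dict()}
    return LTDataset(df, meta=meta, validate=False)


def apply_exclusion(data: LTDataset, min_test_trials: int = 3):
    """Drop infants with fewer than ``min_test_trials`` trials after trial d.

    Returns ``(kept_dataset, report)`` where the report lists the removed ids
    and the exclusion rate.
    """
    info = data.infants()
    n_test = info["n_trials"] - info["n_hab_trials"]
    excluded = info.loc[n_test < int(min_test_trials), "infant_id"].tolist()
    kept = data.subset(set(info["infant_id"]) - set(excluded))
    n_before = len(info)
    report = {
        "excluded_ids": excluded,
        "n_before": int(n_before),
        "n_after": int(n_before - len(excluded)),
        "exclusion_rate": (len(excluded) / n_before) if n_before else 0.0,
        "min_test_trials": int(min_test_trials),
    }
    return kept, report


def write_dataset(data: LTDataset, path) -> None:
    """CSV with the documented schema (UTF-8, header, infant then trial order).

    When the dataset carries generator metadata, a ``<path>.meta.json`` sidecar
    records the seed and config.
    """
    data.df.to_csv(path, index=False, encoding="utf-8")
    if data.meta:
        with open(f"{path}.meta.json", "w", encoding="utf-8") as fh:
            json.dump(data.meta, fh, indent=1, default=str)


def read_dataset(path) -> LTDataset:
    """Read and validate a dataset CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} is missing columns {missing}")
    meta = {}
    try:
        with open(f"{path}.meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
    except (FileNotFoundError, json.JSONDecodeError):
        pass
    return LTDataset(df, meta=meta)
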