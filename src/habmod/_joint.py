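"""Joint log-posteriors (with analytic gradients) for the MCMC fitters.

Two model classes over an unconstrained parameter vector:

* :class:`NoPoolModel` — independent per-infant parameters (alpha, beta, gamma,
  log sigma) with weakly-informative priors.  Because infants are a priori and
  a posteriori independent here, sampling the factorized joint posterior of a
  whole dataset is equivalent to fitting each infant separately.
* :class:`PartialPoolModel` — the hierarchical model: per-infant parameters
  drawn from group-level normals (additive contrast + cohort decomposition;
  dishabituation additionally by habituation-trial count, or a contrast x count
  interaction layout), non-centered, with lognormal pooling of the nuisance
  sigma.

Positive quantities are log-transformed (Jacobian included).  Both classes
expose ``logp_grad(theta)``, ``initial_value(rng)`` and ``constrain(draws)``
which maps unconstrained draws to named constrained variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _loglik
from .data import CONTRASTS, COHORTS, HAB_TRIAL_LEVELS, LTDataset


@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults; all scales on the parameter's native scale."""

    mean_sd: float = 10.0        # population means and no-pooling alpha/beta/gamma
    scale_sd: float = 5.0        # half-normal on population scales
    sigma_sd: float = 5.0        # half-normal on no-pooling sigma
    sigma_log_mean_sd: float = 2.0   # normal on the hierarchical log-sigma mean
    sigma_log_scale_sd: float = 1.0  # half-normal on the hierarchical log-sigma scale
    delta_loc: float = 1.0       # quadratic peak trial
    delta_sd: float = 1.0


def _prepare_obs(dataset: LTDataset, family: str, structure: str, drop_trial=None):
    """Flatten a dataset into per-observation arrays for the likelihood."""
    df = dataset.df
    info = dataset.infants()
    ids = info["infant_id"].tolist()
    pos = {iid: k for k, iid in enumerate(ids)}

    inf = df["infant_id"].map(pos).to_numpy()
    t = df["trial"].to_numpy(dtype=float)
    y = df["lt_seconds"].to_numpy(dtype=float)
    d = df["n_hab_trials"].to_numpy(dtype=float)

    if structure == "ar":
        if drop_trial is not None:
            raise ValueError("censoring is supported for the trend structure only")
        # previous LT within infant (datasets are sorted by infant, trial)
        prev = np.roll(y, 1)
        first = t == 1
        carrier = prev if family == "N" else np.log(np.where(first, 1.0, prev))
        base = np.where(first, 0.0, carrier)
        coef_a = first.astype(float)
        q = (~first).astype(float)
        coef_g = (t - 1 == d).astype(float)
    else:
        base = np.zeros_like(y)
        coef_a = np.ones_like(y)
        q = t  # replaced per-eval by (t - delta)^2 for the quadratic structure
        coef_g = (t > d).astype(float)

    if drop_trial is not None:
        keep = t != float(drop_trial)
        y, t, inf, base, coef_a, q, coef_g = (
            a[keep] for a in (y, t, inf, base, coef_a, q, coef_g)
        )

    return {
        "ids": ids,
        "info": info,
        "y": y,
        "t": t,
        "inf": inf,
        "base": base,
        "coef_a": coef_a,
        "q": q,
        "coef_g": coef_g,
        "n": len(ids),
    }


def _curvature_constants(family, alpha0, sig0):
    """Per-infant expected-information entries in (z, log sigma) coordinates.

    Returns ``(w, c, ss)``: I_zz, I_{z, log sigma} and I_{log sigma, log sigma}
    per observation, evaluated at the crude starts.  Used only to precondition
    the sampler (per-infant block rotations and the diagonal metric).
    """
    from scipy.special import polygamma

    euler = np.euler_gamma
    if family in ("N", "L"):
        w = 1.0 / sig0**2
        c = np.zeros_like(sig0)
        ss = np.full_like(sig0, 2.0)
    elif family == "E":
        w = (np.exp(np.minimum(alpha0, 5.0)) / sig0) ** 2
        c = np.zeros_like(sig0)
        ss = np.full_like(sig0, 2.0)
    elif family == "G":
        w = sig0
        c = sig0.astype(float)
        ss = sig0**2 * polygamma(1, sig0)
    else:  # W
        w = sig0**2
        c = -(1.0 - euler) * sig0
        ss = np.full_like(sig0, np.pi**2 / 6.0 + (1.0 - euler) ** 2)
    return w, c, ss


def _infant_block_info(obs, family, alpha0, sig0, quadratic, delta0):
    """Batch of per-infant 4x4 information matrices in natural coordinates.

    Coordinates (alpha, beta, gamma, log sigma); the mean-structure regressor
    is x = (coef_a, q, coef_g) so the z-block is sum_w x x^T with the
    z/log-sigma cross terms from the family's expected information.
    """
    n = obs["n"]
    inf = obs["inf"]
    q = (obs["t"] - delta0) ** 2 if quadratic else obs["q"]
    w_i, c_i, ss_i = _curvature_constants(family, alpha0, sig0)
    w, c = w_i[inf], c_i[inf]
    xa, xg = obs["coef_a"], obs["coef_g"]
    counts = np.bincount(inf, minlength=n).astype(float)

    def bc(vals):
        return np.bincount(inf, weights=vals, minlength=n)

    info = np.zeros((n, 4, 4))
    info[:, 0, 0] = bc(w * xa * xa)
    info[:, 0, 1] = info[:, 1, 0] = bc(w * xa * q)
    info[:, 0, 2] = info[:, 2, 0] = bc(w * xa * xg)
    info[:, 1, 1] = bc(w * q * q)
    info[:, 1, 2] = info[:, 2, 1] = bc(w * q * xg)
    info[:, 2, 2] = bc(w * xg * xg)
    info[:, 0, 3] = info[:, 3, 0] = bc(c * xa)
    info[:, 1, 3] = info[:, 3, 1] = bc(c * q)
    info[:, 2, 3] = info[:, 3, 2] = bc(c * xg)
    info[:, 3, 3] = ss_i * counts
    return info


def _infant_crude_start(dataset: LTDataset, family: str):
    """Rough data-informed per-infant starting values (alpha, sigma scale)."""
    alpha0, sig0 = [], []
    for _, _, yv, _ in dataset.iter_infants():
        m = float(np.mean(yv))
        if family == "N":
            alpha0.append(m)
            sig0.append(max(float(np.std(yv)), 0.3))
        elif family == "E":
            alpha0.append(float(np.log(m)))
            sig0.append(max(float(np.std(yv)), 0.3))
        elif family == "L":
            alpha0.append(float(np.mean(np.log(yv))))
            sig0.append(max(float(np.std(np.log(yv))), 0.2))
        elif family == "W":
            alpha0.append(float(np.log(m)))
            sig0.append(1.5)
        else:  # G
            alpha0.append(float(np.log(m)))
            sig0.append(2.0)
    return np.asarray(alpha0), np.asarray(sig0)


class _Slicer:
    def __init__(self):
        self.slices = {}
        self.dim = 0

    def add(self, name, size):
        self.slices[name] = slice(self.dim, self.dim + size)
        self.dim += size


class NoPoolModel:
    """Factorized no-pooling posterior over (alpha, beta, gamma, sigma) per infant.

    Each infant's 4-parameter block is sampled in the orthonormal eigenbasis of
    its approximate information matrix (block rotation with unit determinant;
    the model is unchanged) so the sampler sees a well-conditioned, nearly
    axis-aligned posterior despite the strong within-infant collinearity of
    intercept, trial index and dishabituation dummy.
    """

    def __init__(self, dataset, family, structure, priors=None, drop_trial=None,
                 delta=None):
        self.family = family
        self.structure = structure
        self.priors = priors or Priors()
        self.obs = _prepare_obs(dataset, family, structure, drop_trial)
        self.dataset = dataset
        n = self.obs["n"]
        s = _Slicer()
        s.add("alpha", n)
        s.add("beta", n)
        s.add("gamma", n)
        s.add("u_sigma", n)
        self.quadratic = structure == "quadratic"
        if self.quadratic:
            s.add("delta", 1)
        self.slices = s.slices
        self.dim = s.dim
        self.n = n
        alpha0, sig0 = _infant_crude_start(dataset, family)
        self._start = (alpha0, sig0)
        info = _infant_block_info(self.obs, family, alpha0, sig0,
                                  self.quadratic, self.priors.delta_loc)
        prior_diag = np.diag(
            [1.0 / self.priors.mean_sd**2] * 3 + [0.04]
        )
        lam, q = np.linalg.eigh(info + prior_diag[None])
        self._q = q
        self._lam = np.maximum(lam, 1e-12)

    def _natural(self, theta):
        """(alpha, beta, gamma, u_sigma) rows from the rotated coordinates."""
        return np.einsum("nij,jn->in", self._q, theta[: 4 * self.n].reshape(4, self.n))

    def logp_grad(self, theta):
        o = self.obs
        pr = self.priors
        n = self.n
        alpha, beta, gam, u_sig = self._natural(theta)
        with np.errstate(over="ignore"):
            sigma = np.exp(u_sig)
        if not np.all(np.isfinite(sigma)) or np.any(sigma > 1e8):
            return -np.inf, np.zeros(self.dim)
        inf = o["inf"]
        if self.quadratic:
            delta = theta[self.slices["delta"]][0]
            q = (o["t"] - delta) ** 2
        else:
            q = o["q"]
        z = o["coef_a"] * alpha[inf] + q * beta[inf] + o["coef_g"] * gam[inf] + o["base"]
        logp_t, dz, dsig = _loglik.terms(self.family, o["y"], z, sigma[inf])
        ll = float(np.sum(logp_t))
        if not np.isfinite(ll):
            return -np.inf, np.zeros(self.dim)
        a_sum = np.bincount(inf, weights=o["coef_a"] * dz, minlength=n)
        b_sum = np.bincount(inf, weights=q * dz, minlength=n)
        g_sum = np.bincount(inf, weights=o["coef_g"] * dz, minlength=n)
        s_sum = np.bincount(inf, weights=dsig, minlength=n)
        v = pr.mean_sd**2
        gnat = np.stack(
            [
                a_sum - alpha / v,
                b_sum - beta / v,
                g_sum - gam / v,
                sigma * s_sum - sigma**2 / pr.sigma_sd**2 + 1.0,
            ]
        )
        grad = np.empty(self.dim)
        grad[: 4 * n] = np.einsum("nij,in->jn", self._q, gnat).reshape(-1)
        lp = (
            ll
            - 0.5 * (np.sum(alpha**2) + np.sum(beta**2) + np.sum(gam**2)) / v
            - 0.5 * np.sum(sigma**2) / pr.sigma_sd**2
            + np.sum(u_sig)
        )
        if self.quadratic:
            ddelta = float(np.sum(dz * beta[inf] * (-2.0) * (o["t"] - delta)))
            grad[self.slices["delta"]] = (
                ddelta - (delta - pr.delta_loc) / pr.delta_sd**2
            )
            lp += -0.5 * (delta - pr.delta_loc) ** 2 / pr.delta_sd**2
        return lp, grad

    def initial_value(self, rng):
        alpha0, sig0 = self._start
        nat = np.zeros((4, self.n))
        nat[0] = alpha0
        nat[1] = -0.05 if self.family != "N" else -0.2
        nat[3] = np.log(sig0)
        theta = np.zeros(self.dim)
        theta[: 4 * self.n] = np.einsum("nij,in->jn", self._q, nat).reshape(-1)
        if self.quadratic:
            theta[self.slices["delta"]] = self.priors.delta_loc
        return theta + 0.05 * rng.normal(size=self.dim)

    def metric_guess(self):
        """Approximate posterior variances per rotated coordinate."""
        guess = np.ones(self.dim)
        guess[: 4 * self.n] = (1.0 / self._lam).T.reshape(-1)
        if self.quadratic:
            guess[self.slices["delta"]] = min(self.priors.delta_sd**2, 1.0)
        return guess

    def constrain(self, draws):
        """Map unconstrained draws (n_draws, dim) to named constrained series."""
        draws = np.asarray(draws, dtype=float)
        nat = np.einsum(
            "nij,djn->din", self._q, draws[:, : 4 * self.n].reshape(-1, 4, self.n)
        )
        out = {}
        for k, iid in enumerate(self.obs["ids"]):
            out[f"alpha[{iid}]"] = nat[:, 0, k]
            out[f"beta[{iid}]"] = nat[:, 1, k]
            out[f"gamma[{iid}]"] = nat[:, 2, k]
            out[f"sigma[{iid}]"] = np.exp(nat[:, 3, k])
        if self.quadratic:
            out["delta"] = draws[:, self.slices["delta"]][:, 0]
        return out


class PartialPoolModel:
    """Hierarchical partial-pooling posterior, non-centered parametrization."""

    def __init__(self, dataset, family, structure, gamma_effects="main",
                 priors=None, drop_trial=None):
        if gamma_effects not in ("main", "interaction"):
            raise ValueError(f"unknown gamma_effects layout {gamma_effects!r}")
        self.family = family
        self.structure = structure
        self.gamma_effects = gamma_effects
        self.priors = priors or Priors()
        self.obs = _prepare_obs(dataset, family, structure, drop_trial)
        self.dataset = dataset
        info = self.obs["info"]
        n = self.obs["n"]
        self.n = n

        self.b_levels = [c for c in CONTRASTS if c in set(info["contrast"])]
        self.c_levels = [c for c in COHORTS if c in set(info["cohort"])]
        self.d_levels = sorted(set(int(v) for v in info["n_hab_trials"]))
        b_pos = {v: k for k, v in enumerate(self.b_levels)}
        c_pos = {v: k for k, v in enumerate(self.c_levels)}
        d_pos = {v: k for k, v in enumerate(self.d_levels)}
        self.b_idx = info["contrast"].map(b_pos).to_numpy()
        self.c_idx = info["cohort"].map(c_pos).to_numpy()
        self.d_idx = info["n_hab_trials"].astype(int).map(d_pos).to_numpy()
        nb, nc, nd = len(self.b_levels), len(self.c_levels), len(self.d_levels)
        self.bd_idx = self.b_idx * nd + self.d_idx

        s = _Slicer()
        s.add("mu_a_b", nb)
        s.add("mu_a_c", nc)
        s.add("mu_b_b", nb)
        s.add("mu_b_c", nc)
        if gamma_effects == "main":
            s.add("mu_g_b", nb)
            s.add("mu_g_c", nc)
            s.add("mu_g_d", nd)
        else:
            s.add("mu_g_bd", nb * nd)
        s.add("u_scale", 3)       # log population scales for alpha, beta, gamma
        s.add("sigma_hyper", 2)   # mean and log-scale of log sigma_i
        self.quadratic = structure == "quadratic"
        if self.quadratic:
            s.add("delta", 1)
        s.add("raw_a", n)
        s.add("raw_b", n)
        s.add("raw_g", n)
        s.add("raw_s", n)
        self.slices = s.slices
        self.dim = s.dim
        self._build_rotations()

    def _build_rotations(self):
        """Eigenbasis reparametrization of the population-mean blocks.

        The additive decomposition (e.g. mu^alpha_b + mu^alpha_c) is redundant:
        the likelihood constrains only sums, leaving prior-scale ridges that a
        diagonal metric cannot follow.  Each mean block is therefore sampled in
        the orthonormal eigenbasis of its approximate information matrix
        (likelihood curvature + prior); the iid normal prior is rotation
        invariant, so the model is unchanged while the posterior becomes
        axis-aligned for the sampler.
        """
        alpha0, sig0 = _infant_crude_start(self.dataset, self.family)
        self._start = (alpha0, sig0)
        info4 = _infant_block_info(self.obs, self.family, alpha0, sig0,
                                   self.quadratic, self.priors.delta_loc)
        ia, ib, ig = info4[:, 0, 0], info4[:, 1, 1], info4[:, 2, 2]
        self._infant_fisher = (ia, ib, ig)
        # non-centered raw blocks: scale the natural-coordinate information by
        # the anticipated population scales; the standard-normal raw prior is
        # rotation invariant, so the per-infant eigenbasis is again free
        s_a0 = max(float(np.std(alpha0)), 0.1)
        self._raw_scale0 = np.array([s_a0, 0.05, 0.1, 0.3])
        d0 = self._raw_scale0
        raw_info = d0[None, :, None] * info4 * d0[None, None, :] + np.eye(4)[None]
        lam_r, q_r = np.linalg.eigh(raw_info)
        self._raw_q = q_r
        self._raw_lam = np.maximum(lam_r, 1e-12)
        sl = self.slices
        nb, nc, nd = len(self.b_levels), len(self.c_levels), len(self.d_levels)
        v_mean = self.priors.mean_sd**2

        def _block(names, idx_parts, weights):
            start = sl[names[0]].start
            stop = sl[names[-1]].stop
            p = stop - start
            a_mat = np.zeros((self.n, p))
            off = 0
            for name, idx in zip(names, idx_parts):
                width = sl[name].stop - sl[name].start
                a_mat[np.arange(self.n), off + idx] = 1.0
                off += width
            info = a_mat.T @ (weights[:, None] * a_mat) + np.eye(p) / v_mean
            lam, q = np.linalg.eigh(info)
            return slice(start, stop), q, np.maximum(lam, 1e-12)

        blocks = [
            _block(("mu_a_b", "mu_a_c"), (self.b_idx, self.c_idx), ia),
            _block(("mu_b_b", "mu_b_c"), (self.b_idx, self.c_idx), ib),
        ]
        if self.gamma_effects == "main":
            blocks.append(
                _block(("mu_g_b", "mu_g_c", "mu_g_d"),
                       (self.b_idx, self.c_idx, self.d_idx), ig)
            )
        else:
            blocks.append(_block(("mu_g_bd",), (self.bd_idx,), ig))
        self._blocks = blocks

    def _to_mu(self, theta):
        """Rotate the sampled coordinates into the natural mean parametrization."""
        mu = theta.copy()
        for bsl, q, _ in self._blocks:
            mu[bsl] = q @ theta[bsl]
        return mu

    # -- mean structure helpers ------------------------------------------
    def _gamma_mean(self, mu):
        sl = self.slices
        if self.gamma_effects == "main":
            return (
                mu[sl["mu_g_b"]][self.b_idx]
                + mu[sl["mu_g_c"]][self.c_idx]
                + mu[sl["mu_g_d"]][self.d_idx]
            )
        return mu[sl["mu_g_bd"]][self.bd_idx]

    def logp_grad(self, theta):
        o = self.obs
        pr = self.priors
        sl = self.slices
        n = self.n
        inf = o["inf"]

        with np.errstate(over="ignore"):
            scales = np.exp(theta[sl["u_scale"]])
            mu_ls, u_tau = theta[sl["sigma_hyper"]]
            tau = np.exp(u_tau)
        # the half-normal priors put no mass remotely near such scales; cut the
        # trajectory off before downstream arithmetic overflows
        if not np.all(np.isfinite(scales)) or np.any(scales > 1e8) or tau > 1e8:
            return -np.inf, np.zeros(self.dim)
        s_a, s_b, s_g = scales

        raw_a, raw_b, raw_g, raw_s = np.einsum(
            "nij,jn->in", self._raw_q, theta[-4 * n:].reshape(4, n)
        )

        mu = self._to_mu(theta)
        mean_a = mu[sl["mu_a_b"]][self.b_idx] + mu[sl["mu_a_c"]][self.c_idx]
        mean_b = mu[sl["mu_b_b"]][self.b_idx] + mu[sl["mu_b_c"]][self.c_idx]
        mean_g = self._gamma_mean(mu)
        alpha = mean_a + s_a * raw_a
        beta = mean_b + s_b * raw_b
        gam = mean_g + s_g * raw_g
        with np.errstate(over="ignore"):
            sigma = np.exp(mu_ls + tau * raw_s)
        if not np.all(np.isfinite(sigma)) or np.any(sigma > 1e8):
            return -np.inf, np.zeros(self.dim)

        if self.quadratic:
            delta = theta[sl["delta"]][0]
            q = (o["t"] - delta) ** 2
        else:
            q = o["q"]
        z = o["coef_a"] * alpha[inf] + q * beta[inf] + o["coef_g"] * gam[inf] + o["base"]
        logp_t, dz, dsig = _loglik.terms(self.family, o["y"], z, sigma[inf])
        ll = float(np.sum(logp_t))
        if not np.isfinite(ll):
            return -np.inf, np.zeros(self.dim)

        a_sum = np.bincount(inf, weights=o["coef_a"] * dz, minlength=n)
        b_sum = np.bincount(inf, weights=q * dz, minlength=n)
        g_sum = np.bincount(inf, weights=o["coef_g"] * dz, minlength=n)
        s_sum = np.bincount(inf, weights=dsig, minlength=n)

        grad = np.empty(self.dim)
        v_mean = pr.mean_sd**2

        def _group_grad(name, per_infant, idx, nlev):
            # data part only; the prior and rotation are applied per block below
            grad[sl[name]] = np.bincount(idx, weights=per_infant, minlength=nlev)

        _group_grad("mu_a_b", a_sum, self.b_idx, len(self.b_levels))
        _group_grad("mu_a_c", a_sum, self.c_idx, len(self.c_levels))
        _group_grad("mu_b_b", b_sum, self.b_idx, len(self.b_levels))
        _group_grad("mu_b_c", b_sum, self.c_idx, len(self.c_levels))
        if self.gamma_effects == "main":
            _group_grad("mu_g_b", g_sum, self.b_idx, len(self.b_levels))
            _group_grad("mu_g_c", g_sum, self.c_idx, len(self.c_levels))
            _group_grad("mu_g_d", g_sum, self.d_idx, len(self.d_levels))
        else:
            _group_grad("mu_g_bd", g_sum, self.bd_idx,
                        len(self.b_levels) * len(self.d_levels))
        for bsl, q, _ in self._blocks:
            grad[bsl] = q.T @ grad[bsl] - theta[bsl] / v_mean

        sig_dsig = sigma * s_sum
        gnat_raw = np.stack(
            [
                s_a * a_sum - raw_a,
                s_b * b_sum - raw_b,
                s_g * g_sum - raw_g,
                tau * sig_dsig - raw_s,
            ]
        )
        grad[-4 * n:] = np.einsum("nij,in->jn", self._raw_q, gnat_raw).reshape(-1)
        v_scale = pr.scale_sd**2
        grad[sl["u_scale"]] = [
            s_a * float(np.dot(raw_a, a_sum)) - s_a**2 / v_scale + 1.0,
            s_b * float(np.dot(raw_b, b_sum)) - s_b**2 / v_scale + 1.0,
            s_g * float(np.dot(raw_g, g_sum)) - s_g**2 / v_scale + 1.0,
        ]
        grad[sl["sigma_hyper"]] = [
            float(np.sum(sig_dsig)) - mu_ls / pr.sigma_log_mean_sd**2,
            tau * float(np.dot(raw_s, sig_dsig))
            - tau**2 / pr.sigma_log_scale_sd**2 + 1.0,
        ]

        mu_block = np.concatenate(
            [theta[sl[k]] for k in sl
             if k.startswith("mu_") and k != "mu_g_bd"]
            + ([theta[sl["mu_g_bd"]]] if self.gamma_effects == "interaction" else [])
        )
        lp = (
            ll
            - 0.5 * float(np.sum(mu_block**2)) / v_mean
            - 0.5 * float(np.sum(raw_a**2) + np.sum(raw_b**2) + np.sum(raw_g**2)
                          + np.sum(raw_s**2))
            - 0.5 * float(np.sum(scales**2)) / v_scale + float(np.sum(theta[sl["u_scale"]]))
            - 0.5 * mu_ls**2 / pr.sigma_log_mean_sd**2
            - 0.5 * tau**2 / pr.sigma_log_scale_sd**2 + u_tau
        )
        if self.quadratic:
            ddelta = float(np.sum(dz * beta[inf] * (-2.0) * (o["t"] - delta)))
            grad[sl["delta"]] = ddelta - (delta - pr.delta_loc) / pr.delta_sd**2
            lp += -0.5 * (delta - pr.delta_loc) ** 2 / pr.delta_sd**2
        return lp, grad

    def initial_value(self, rng):
        alpha0, sig0 = _infant_crude_start(self.dataset, self.family)
        sl = self.slices
        theta = np.zeros(self.dim)
        # put the grand mean on the contrast component, zero on the cohort one
        for k in range(len(self.b_levels)):
            sel = self.b_idx == k
            theta[sl["mu_a_b"]][k] = float(np.mean(alpha0[sel]))
        theta[sl["mu_b_b"]] = -0.05 if self.family != "N" else -0.2
        s_a0 = max(float(np.std(alpha0)), 0.1)
        theta[sl["u_scale"]] = np.log([s_a0, 0.05, 0.1])
        mean_a0 = theta[sl["mu_a_b"]][self.b_idx]
        theta[sl["raw_a"]] = (alpha0 - mean_a0) / s_a0
        theta[sl["sigma_hyper"]] = [float(np.mean(np.log(sig0))), np.log(0.3)]
        if self.quadratic:
            theta[sl["delta"]] = self.priors.delta_loc
        for bsl, q, _ in self._blocks:
            theta[bsl] = q.T @ theta[bsl]
        n = self.n
        theta[-4 * n:] = np.einsum(
            "nij,in->jn", self._raw_q, theta[-4 * n:].reshape(4, n)
        ).reshape(-1)
        return theta + 0.05 * rng.normal(size=self.dim)

    def metric_guess(self):
        """Approximate posterior variances per coordinate (metric preconditioner).

        Crude curvature bookkeeping: per-infant information sums for the
        non-centered raws, block eigenvalues for the rotated population means,
        1/n-type scales for hyperparameters.  Only preconditions the sampler.
        """
        sl = self.slices
        n = self.n
        guess = np.ones(self.dim)
        guess[-4 * n:] = (1.0 / self._raw_lam).T.reshape(-1)
        counts = np.bincount(self.obs["inf"], minlength=n).astype(float)
        for bsl, _, lam in self._blocks:
            guess[bsl] = 1.0 / lam
        guess[sl["u_scale"]] = 1.0 / (0.5 * n + 1.0)
        guess[sl["sigma_hyper"]] = [
            1.0 / (0.25 * float(counts.sum()) + 1.0),
            1.0 / (0.5 * n + 1.0),
        ]
        if self.quadratic:
            guess[sl["delta"]] = min(self.priors.delta_sd**2, 1.0)
        return guess

    def constrain(self, draws):
        draws = np.array(draws, dtype=float)
        for bsl, q, _ in self._blocks:
            draws[:, bsl] = draws[:, bsl] @ q.T
        sl = self.slices
        out = {}
        scales = np.exp(draws[:, sl["u_scale"]])
        out["scale_alpha"] = scales[:, 0]
        out["scale_beta"] = scales[:, 1]
        out["scale_gamma"] = scales[:, 2]
        mu_ls = draws[:, sl["sigma_hyper"]][:, 0]
        tau = np.exp(draws[:, sl["sigma_hyper"]][:, 1])
        out["sigma_log_mean"] = mu_ls
        out["sigma_log_scale"] = tau
        for k, lev in enumerate(self.b_levels):
            out[f"mu_alpha_contrast[{lev}]"] = draws[:, sl["mu_a_b"]][:, k]
            out[f"mu_beta_contrast[{lev}]"] = draws[:, sl["mu_b_b"]][:, k]
        for k, lev in enumerate(self.c_levels):
            out[f"mu_alpha_cohort[{lev}]"] = draws[:, sl["mu_a_c"]][:, k]
            out[f"mu_beta_cohort[{lev}]"] = draws[:, sl["mu_b_c"]][:, k]
        if self.gamma_effects == "main":
            for k, lev in enumerate(self.b_levels):
                out[f"mu_gamma_contrast[{lev}]"] = draws[:, sl["mu_g_b"]][:, k]
            for k, lev in enumerate(self.c_levels):
                out[f"mu_gamma_cohort[{lev}]"] = draws[:, sl["mu_g_c"]][:, k]
            for k, lev in enumerate(self.d_levels):
                out[f"mu_gamma_hab[{lev}]"] = draws[:, sl["mu_g_d"]][:, k]
        else:
            nd = len(self.d_levels)
            for kb, lb in enumerate(self.b_levels):
                for kd, ld in enumerate(self.d_levels):
                    out[f"mu_gamma_cell[{lb},{ld}]"] = (
                        draws[:, sl["mu_g_bd"]][:, kb * nd + kd]
                    )
        if self.quadratic:
            out["delta"] = draws[:, sl["delta"]][:, 0]

        mean_a = (
            draws[:, sl["mu_a_b"]][:, self.b_idx]
            + draws[:, sl["mu_a_c"]][:, self.c_idx]
        )
        mean_b = (
            draws[:, sl["mu_b_b"]][:, self.b_idx]
            + draws[:, sl["mu_b_c"]][:, self.c_idx]
        )
        if self.gamma_effects == "main":
            mean_g = (
                draws[:, sl["mu_g_b"]][:, self.b_idx]
                + draws[:, sl["mu_g_c"]][:, self.c_idx]
                + draws[:, sl["mu_g_d"]][:, self.d_idx]
            )
        else:
            mean_g = draws[:, sl["mu_g_bd"]][:, self.bd_idx]
        n = self.n
        raw_nat = np.einsum(
            "nij,djn->din", self._raw_q, draws[:, -4 * n:].reshape(-1, 4, n)
        )
        alpha = mean_a + scales[:, [0]] * raw_nat[:, 0, :]
        beta = mean_b + scales[:, [1]] * raw_nat[:, 1, :]
        gam = mean_g + scales[:, [2]] * raw_nat[:, 2, :]
        sigma = np.exp(mu_ls[:, None] + tau[:, None] * raw_nat[:, 3, :])
        for k, iid in enumerate(self.obs["ids"]):
            out[f"alpha[{iid}]"] = alpha[:, k]
            out[f"beta[{iid}]"] = beta[:, k]
            out[f"gamma[{iid}]"] = gam[:, k]
            out[f"sigma[{iid}]"] = sigma[:, k]
        return out
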