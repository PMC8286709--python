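"""No-U-Turn sampler on an unconstrained parameter space.

Self-contained gradient-based MCMC used by the model fitters: the original
recursive NUTS with a slice variable (Hoffman & Gelman's formulation), plus the
adaptations customary in modern implementations — dual-averaging step-size
tuning toward a target acceptance statistic and windowed estimation of a
diagonal metric during warm-up.  Models supply ``logp_grad(theta) ->
(logp, grad)``; points with non-finite log-density are treated as divergent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim), post-warmup
    divergences: int
    step_size: float
    mean_accept: float
    max_treedepth_hits: int


def _energy(lp, r, inv_m):
    with np.errstate(over="ignore", invalid="ignore"):
        kin = float(np.dot(r * r, inv_m))
    return lp - 0.5 * kin


class _Tree:
    __slots__ = ("minus", "plus", "prop", "n", "s", "alpha", "n_alpha", "n_div")

    def __init__(self, minus, plus, prop, n, s, alpha, n_alpha, n_div):
        self.minus = minus
        self.plus = plus
        self.prop = prop
        self.n = n
        self.s = s
        self.alpha = alpha
        self.n_alpha = n_alpha
        self.n_div = n_div


def _leapfrog(state, eps, logp_grad, inv_m):
    theta, r, lp, grad = state
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_m * r1
    lp1, grad1 = logp_grad(theta1)
    if not np.isfinite(lp1):
        lp1 = -np.inf
        grad1 = np.zeros_like(theta1)
    else:
        grad1 = np.where(np.isfinite(grad1), grad1, 0.0)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, lp1, grad1


def _no_uturn(minus, plus, inv_m):
    dtheta = plus[0] - minus[0]
    return (
        float(np.dot(dtheta, inv_m * minus[1])) >= 0.0
        and float(np.dot(dtheta, inv_m * plus[1])) >= 0.0
    )


def _build_tree(state, log_u, v, j, eps, h0, logp_grad, inv_m, rng):
    if j == 0:
        new = _leapfrog(state, v * eps, logp_grad, inv_m)
        h = _energy(new[2], new[1], inv_m)
        dh = h - h0
        if not np.isfinite(dh):
            dh = -np.inf
        divergent = dh < -_MAX_DELTA_H
        n = 1 if log_u <= dh else 0
        alpha = min(1.0, math.exp(min(dh, 0.0))) if np.isfinite(dh) else 0.0
        return _Tree(new, new, new, n, not divergent, alpha, 1, int(divergent))
    t1 = _build_tree(state, log_u, v, j - 1, eps, h0, logp_grad, inv_m, rng)
    if not t1.s:
        return t1
    if v > 0:
        t2 = _build_tree(t1.plus, log_u, v, j - 1, eps, h0, logp_grad, inv_m, rng)
        minus, plus = t1.minus, t2.plus
    else:
        t2 = _build_tree(t1.minus, log_u, v, j - 1, eps, h0, logp_grad, inv_m, rng)
        minus, plus = t2.minus, t1.plus
    n = t1.n + t2.n
    prop = t1.prop
    if t2.n > 0 and rng.random() < t2.n / max(n, 1):
        prop = t2.prop
    s = t2.s and _no_uturn(minus, plus, inv_m)
    return _Tree(
        minus, plus, prop, n, s,
        t1.alpha + t2.alpha, t1.n_alpha + t2.n_alpha, t1.n_div + t2.n_div,
    )


def _find_step_size(state, inv_m, logp_grad, rng, eps=1.0):
    """Coarse initial step size: double/halve until the one-step accept ratio crosses 1/2."""
    h0 = _energy(state[2], state[1], inv_m)
    new = _leapfrog(state, eps, logp_grad, inv_m)
    dh = _energy(new[2], new[1], inv_m) - h0
    if not np.isfinite(dh):
        dh = -np.inf
    a = 1.0 if dh > math.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**a
        new = _leapfrog(state, eps, logp_grad, inv_m)
        dh = _energy(new[2], new[1], inv_m) - h0
        if not np.isfinite(dh):
            dh = -np.inf
        if a * dh <= a * math.log(0.5):
            break
    return max(eps, 1e-10)


def _adaptation_windows(n_warmup):
    """(start, end) index pairs of metric-estimation windows within warm-up."""
    if n_warmup < 150:
        return []
    first = min(75, n_warmup // 5)
    last_buffer = min(50, n_warmup // 5)
    end_adapt = n_warmup - last_buffer
    windows = []
    start, size = first, 25
    while start < end_adapt:
        end = min(start + size, end_adapt)
        if end_adapt - end < size:  # absorb the remainder into the last window
            end = end_adapt
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def sample_chain(
    logp_grad,
    theta0,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    metric_guess=None,
) -> ChainResult:
    """Run one NUTS chain; returns the ``n_iter - n_warmup`` post-warmup draws.

    ``metric_guess`` optionally supplies approximate per-coordinate posterior
    variances; it seeds the diagonal metric and regularizes the windowed
    estimates, which matters most for short warm-ups.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-density")
    if metric_guess is None:
        guess = np.ones(dim)
    else:
        guess = np.clip(np.asarray(metric_guess, dtype=float), 1e-8, 1e4)
    inv_m = guess.copy()
    state = (theta, np.zeros(dim), lp, grad)

    eps = _find_step_size(
        (theta, rng.normal(size=dim), lp, grad), inv_m, logp_grad, rng
    )
    # dual averaging state
    mu = math.log(10.0 * eps)
    h_bar, log_eps_bar, adapt_count = 0.0, 0.0, 0

    windows = _adaptation_windows(n_warmup)
    window_idx = 0
    window_buf = []

    draws = np.empty((max(n_iter - n_warmup, 0), dim))
    divergences = 0
    depth_hits = 0
    accept_sum, accept_n = 0.0, 0

    for it in range(n_iter):
        r0 = rng.normal(size=dim) / np.sqrt(inv_m)
        cur = (state[0], r0, state[2], state[3])
        h0 = _energy(cur[2], r0, inv_m)
        log_u = math.log(max(rng.random(), 1e-300))
        minus = plus = prop = cur
        n, s, depth = 1, True, 0
        it_alpha, it_n_alpha = 0.0, 0
        while s:
            v = 1 if rng.random() < 0.5 else -1
            seed_state = plus if v > 0 else minus
            tree = _build_tree(
                seed_state, log_u, v, depth, eps, h0, logp_grad, inv_m, rng
            )
            if v > 0:
                plus = tree.plus
            else:
                minus = tree.minus
            it_alpha += tree.alpha
            it_n_alpha += tree.n_alpha
            if it >= n_warmup:
                divergences += tree.n_div
            if tree.s:
                if tree.n > 0 and rng.random() < tree.n / max(n, 1):
                    prop = tree.prop
                n += tree.n
                s = _no_uturn(minus, plus, inv_m)
            else:
                s = False
            depth += 1
            if depth >= max_treedepth:
                if it >= n_warmup and s:
                    depth_hits += 1
                break
        state = (prop[0], np.zeros(dim), prop[2], prop[3])
        alpha_stat = it_alpha / max(it_n_alpha, 1)

        if it < n_warmup:
            # dual averaging step-size update
            adapt_count += 1
            frac = 1.0 / (adapt_count + 10.0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha_stat)
            log_eps = mu - math.sqrt(adapt_count) / 0.05 * h_bar
            w = adapt_count ** -0.75
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            # windowed diagonal metric estimation
            if window_idx < len(windows):
                w_start, w_end = windows[window_idx]
                if w_start <= it < w_end:
                    window_buf.append(state[0].copy())
                if it == w_end - 1 and len(window_buf) >= 10:
                    arr = np.asarray(window_buf)
                    nw = arr.shape[0]
                    var = arr.var(axis=0, ddof=1)
                    inv_m = (nw / (nw + 5.0)) * var + guess * (5.0 / (nw + 5.0))
                    inv_m = np.maximum(inv_m, 1e-10)
                    window_buf = []
                    window_idx += 1
                    eps = _find_step_size(
                        (state[0], rng.normal(size=dim) / np.sqrt(inv_m),
                         state[2], state[3]),
                        inv_m, logp_grad, rng, eps=eps,
                    )
                    mu = math.log(10.0 * eps)
                    h_bar, log_eps_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar) if adapt_count > 0 else eps
        else:
            draws[it - n_warmup] = state[0]
            accept_sum += alpha_stat
            accept_n += 1

    return ChainResult(
        draws=draws,
        divergences=divergences,
        step_size=eps,
        mean_accept=accept_sum / max(accept_n, 1),
        max_treedepth_hits=depth_hits,
    )
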