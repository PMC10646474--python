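"""A self-contained No-U-Turn sampler.

Multinomial NUTS (trajectory states weighted by exp(-H)) with dual-averaging
step-size adaptation and a diagonal mass matrix estimated during warmup in
Stan-style expanding windows.  The sampler takes an arbitrary differentiable
log-density, works in an unconstrained space, and is deterministic given a
numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_MAX_DELTA_H = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class ChainStats:
    accept_prob: list = field(default_factory=list)
    n_divergent: int = 0
    tree_depths: list = field(default_factory=list)
    step_size: float = float("nan")
    inv_mass: np.ndarray | None = None


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(r * inv_mass, r))


class _Tree:
    """One side of a NUTS trajectory (recursive doubling)."""

    __slots__ = (
        "theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
        "theta_prop", "logp_prop", "grad_prop", "log_weight",
        "sum_r", "turning", "diverging", "sum_accept", "n_steps",
    )


def _build_tree(logp_grad, state, depth, direction, eps, inv_mass, h0, rng):
    if depth == 0:
        theta, r, grad = (
            (state.theta_p, state.r_p, state.grad_p)
            if direction == 1
            else (state.theta_m, state.r_m, state.grad_m)
        )
        theta, r, logp, grad = _leapfrog(logp_grad, theta, r, grad, direction * eps, inv_mass)
        h = -logp + _kinetic(r, inv_mass)
        delta = h0 - h  # log weight relative to the initial state
        t = _Tree()
        t.theta_m = t.theta_p = theta
        t.r_m = t.r_p = r
        t.grad_m = t.grad_p = grad
        t.theta_prop, t.logp_prop, t.grad_prop = theta, logp, grad
        t.log_weight = delta if np.isfinite(delta) else -np.inf
        t.sum_r = r.copy()
        t.diverging = not np.isfinite(delta) or (-delta) > _MAX_DELTA_H
        t.turning = False
        t.sum_accept = min(1.0, math.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        t.n_steps = 1
        return t
    first = _build_tree(logp_grad, state, depth - 1, direction, eps, inv_mass, h0, rng)
    if first.diverging or first.turning:
        return first
    inner = _Tree()
    if direction == 1:
        inner.theta_m, inner.r_m, inner.grad_m = first.theta_p, first.r_p, first.grad_p
        inner.theta_p, inner.r_p, inner.grad_p = first.theta_p, first.r_p, first.grad_p
    else:
        inner.theta_m, inner.r_m, inner.grad_m = first.theta_m, first.r_m, first.grad_m
        inner.theta_p, inner.r_p, inner.grad_p = first.theta_m, first.r_m, first.grad_m
    second = _build_tree(logp_grad, inner, depth - 1, direction, eps, inv_mass, h0, rng)
    # merge
    if direction == 1:
        first.theta_p, first.r_p, first.grad_p = second.theta_p, second.r_p, second.grad_p
    else:
        first.theta_m, first.r_m, first.grad_m = second.theta_m, second.r_m, second.grad_m
    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.isfinite(second.log_weight) and math.log(rng.random() + 1e-300) < second.log_weight - total:
        first.theta_prop = second.theta_prop
        first.logp_prop = second.logp_prop
        first.grad_prop = second.grad_prop
    first.log_weight = total
    first.sum_r = first.sum_r + second.sum_r
    first.sum_accept += second.sum_accept
    first.n_steps += second.n_steps
    first.diverging = second.diverging
    first.turning = second.turning or _uturn(first, inv_mass)
    return first


def _uturn(tree, inv_mass) -> bool:
    v_m = inv_mass * tree.r_m
    v_p = inv_mass * tree.r_p
    return bool(np.dot(tree.sum_r, v_m) <= 0 or np.dot(tree.sum_r, v_p) <= 0)


def _nuts_step(logp_grad, theta, logp, grad, eps, inv_mass, rng, max_depth):
    r0 = rng.normal(size=theta.size) / np.sqrt(inv_mass)
    h0 = -logp + _kinetic(r0, inv_mass)
    state = _Tree()
    state.theta_m = state.theta_p = theta
    state.r_m = state.r_p = r0
    state.grad_m = state.grad_p = grad
    state.theta_prop, state.logp_prop, state.grad_prop = theta, logp, grad
    state.log_weight = 0.0
    state.sum_r = r0.copy()
    state.turning = state.diverging = False
    sum_accept, n_steps = 0.0, 0
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        sub = _build_tree(logp_grad, state, depth, direction, eps, inv_mass, h0, rng)
        sum_accept += sub.sum_accept
        n_steps += sub.n_steps
        if sub.diverging:
            return state.theta_prop, state.logp_prop, state.grad_prop, sum_accept / n_steps, depth, True
        if not sub.turning:
            total = np.logaddexp(state.log_weight, sub.log_weight)
            if math.log(rng.random() + 1e-300) < sub.log_weight - total:
                state.theta_prop = sub.theta_prop
                state.logp_prop = sub.logp_prop
                state.grad_prop = sub.grad_prop
            state.log_weight = total
        if direction == 1:
            state.theta_p, state.r_p, state.grad_p = sub.theta_p, sub.r_p, sub.grad_p
        else:
            state.theta_m, state.r_m, state.grad_m = sub.theta_m, sub.r_m, sub.grad_m
        state.sum_r = state.sum_r + sub.sum_r
        if sub.turning or _uturn(state, inv_mass):
            break
        depth += 1
    return state.theta_prop, state.logp_prop, state.grad_prop, sum_accept / max(n_steps, 1), depth + 1, False


def _init_step_size(logp_grad, theta, logp, grad, inv_mass, rng):
    eps = 1.0
    r = rng.normal(size=theta.size) / np.sqrt(inv_mass)
    h0 = -logp + _kinetic(r, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    h1 = -logp1 + _kinetic(r1, inv_mass) if np.isfinite(logp1) else np.inf
    direction = 1 if (h0 - h1) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        h1 = -logp1 + _kinetic(r1, inv_mass) if np.isfinite(logp1) else np.inf
        if direction * (h0 - h1) < direction * math.log(0.5):
            break
    return eps


def nuts(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_depth: int = 10,
) -> tuple[np.ndarray, ChainStats]:
    """Run one NUTS chain; returns post-warmup draws and adaptation stats."""
    theta = np.asarray(theta0, dtype=float).copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    d = theta.size
    inv_mass = np.ones(d)
    eps = _init_step_size(logp_grad, theta, logp, grad, inv_mass, rng)

    # dual averaging state; m_adapt restarts whenever the mass matrix changes
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-adaptation windows: fast start, expanding slow windows, fast end
    init_buf = min(75, max(1, int(0.15 * n_warmup)))
    term_buf = min(50, max(1, int(0.10 * n_warmup)))
    slow_end = n_warmup - term_buf
    window_end = init_buf + 25
    welford_n, welford_mean, welford_m2 = 0, np.zeros(d), np.zeros(d)

    stats = ChainStats()
    draws = np.empty((n_draws, d))
    for it in range(n_warmup + n_draws):
        theta, logp, grad, accept, depth, div = _nuts_step(
            logp_grad, theta, logp, grad, eps, inv_mass, rng, max_depth
        )
        if it < n_warmup:
            m_adapt += 1
            m = m_adapt
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept) / (m + t0)
            log_eps = mu - math.sqrt(m) / gamma * h_bar
            w = m**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if init_buf <= it < slow_end:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
                if it + 1 == min(window_end, slow_end) and welford_n > 4:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = var * (welford_n / (welford_n + 5.0)) + 1e-3 * (
                        5.0 / (welford_n + 5.0)
                    )
                    welford_n, welford_mean, welford_m2 = 0, np.zeros(d), np.zeros(d)
                    eps = _init_step_size(logp_grad, theta, logp, grad, inv_mass, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
                    window_end = it + 1 + 2 * (window_end - init_buf)
            if it + 1 == n_warmup:
                eps = math.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = theta
            stats.accept_prob.append(accept)
            stats.tree_depths.append(depth)
            if div:
                stats.n_divergent += 1
    stats.step_size = eps
    stats.inv_mass = inv_mass
    return draws, stats
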