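"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC engine for the hierarchical count models:
multinomial NUTS (dynamic Hamiltonian Monte Carlo) with a Stan-like warmup
schedule — an initial step-size phase, expanding windows that estimate a
diagonal mass matrix from the warmup draws, and a final step-size phase.
The model supplies a joint log-density and gradient on an unconstrained
parameter vector; everything here is distribution-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NutsResult"]

_MAX_DELTA_H = 1000.0  # divergence threshold on energy error


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_stat: np.ndarray
    tree_depth: np.ndarray
    divergences: int
    step_size: float
    inv_mass: np.ndarray


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "g_prop", "logp_prop", "log_w", "sum_accept", "n_leaf",
        "turning", "diverging",
    )


def _leaf(q, p, g, logp, h0, inv_mass):
    t = _Tree()
    t.q_minus = t.q_plus = t.q_prop = q
    t.p_minus = t.p_plus = p
    t.g_minus = t.g_plus = t.g_prop = g
    t.logp_prop = logp
    h = -logp + 0.5 * np.dot(p, inv_mass * p)
    t.log_w = h0 - h
    t.sum_accept = min(1.0, np.exp(h0 - h))
    t.n_leaf = 1
    t.diverging = (h - h0) > _MAX_DELTA_H or not np.isfinite(h)
    t.turning = False
    return t


def _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _merge(rng, left: _Tree, right: _Tree, forward: bool, inv_mass) -> _Tree:
    t = _Tree()
    if forward:
        t.q_minus, t.p_minus, t.g_minus = left.q_minus, left.p_minus, left.g_minus
        t.q_plus, t.p_plus, t.g_plus = right.q_plus, right.p_plus, right.g_plus
    else:
        t.q_minus, t.p_minus, t.g_minus = right.q_minus, right.p_minus, right.g_minus
        t.q_plus, t.p_plus, t.g_plus = left.q_plus, left.p_plus, left.g_plus
    t.log_w = np.logaddexp(left.log_w, right.log_w)
    # multinomial sampling among leaves
    if np.log(rng.uniform()) < right.log_w - t.log_w:
        t.q_prop, t.g_prop, t.logp_prop = right.q_prop, right.g_prop, right.logp_prop
    else:
        t.q_prop, t.g_prop, t.logp_prop = left.q_prop, left.g_prop, left.logp_prop
    t.sum_accept = left.sum_accept + right.sum_accept
    t.n_leaf = left.n_leaf + right.n_leaf
    t.diverging = left.diverging or right.diverging
    t.turning = left.turning or right.turning or _uturn(
        t.q_minus, t.q_plus, t.p_minus, t.p_plus, inv_mass
    )
    return t


def _build(rng, logp_grad, q, p, g, direction, depth, eps, h0, inv_mass) -> _Tree:
    if depth == 0:
        eps_d = direction * eps
        p = p + 0.5 * eps_d * g
        q = q + eps_d * inv_mass * p
        logp, g = logp_grad(q)
        p = p + 0.5 * eps_d * g
        return _leaf(q, p, g, logp, h0, inv_mass)
    first = _build(rng, logp_grad, q, p, g, direction, depth - 1, eps, h0, inv_mass)
    if first.diverging or first.turning:
        return first
    if direction == 1:
        q2, p2, g2 = first.q_plus, first.p_plus, first.g_plus
    else:
        q2, p2, g2 = first.q_minus, first.p_minus, first.g_minus
    second = _build(rng, logp_grad, q2, p2, g2, direction, depth - 1, eps, h0, inv_mass)
    return _merge(rng, first, second, direction == 1, inv_mass)


def _nuts_step(rng, logp_grad, q, g, logp, eps, inv_mass, max_treedepth):
    dim = len(q)
    p = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * np.dot(p, inv_mass * p)
    tree = _leaf(q, p, g, logp, h0, inv_mass)
    tree.sum_accept, tree.n_leaf = 0.0, 0  # the root does not count
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build(rng, logp_grad, tree.q_plus, tree.p_plus, tree.g_plus,
                         1, depth, eps, h0, inv_mass)
        else:
            sub = _build(rng, logp_grad, tree.q_minus, tree.p_minus, tree.g_minus,
                         -1, depth, eps, h0, inv_mass)
        if sub.diverging:
            tree.diverging = True
            break
        if not sub.turning:
            # biased progressive sampling toward the new subtree
            if np.log(rng.uniform()) < sub.log_w - tree.log_w:
                tree.q_prop, tree.g_prop, tree.logp_prop = sub.q_prop, sub.g_prop, sub.logp_prop
        tree.sum_accept += sub.sum_accept
        tree.n_leaf += sub.n_leaf
        if direction == 1:
            tree.q_plus, tree.p_plus, tree.g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            tree.q_minus, tree.p_minus, tree.g_minus = sub.q_minus, sub.p_minus, sub.g_minus
        tree.log_w = np.logaddexp(tree.log_w, sub.log_w)
        depth += 1
        if sub.turning or _uturn(tree.q_minus, tree.q_plus, tree.p_minus, tree.p_plus, inv_mass):
            break
    accept = tree.sum_accept / max(tree.n_leaf, 1)
    return tree.q_prop, tree.g_prop, tree.logp_prop, accept, depth, tree.diverging


def _initial_step_size(rng, logp_grad, q, g, logp, inv_mass) -> float:
    eps = 1.0
    dim = len(q)
    p = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * np.dot(p, inv_mass * p)

    def energy_error(eps):
        p1 = p + 0.5 * eps * g
        q1 = q + eps * inv_mass * p1
        logp1, g1 = logp_grad(q1)
        p1 = p1 + 0.5 * eps * g1
        h1 = -logp1 + 0.5 * np.dot(p1, inv_mass * p1)
        return h0 - h1 if np.isfinite(h1) else -np.inf

    direction = 1 if energy_error(eps) > np.log(0.5) else -1
    for _ in range(50):
        if direction == 1 and energy_error(eps) <= np.log(0.5):
            break
        if direction == -1 and energy_error(eps) >= np.log(0.5):
            break
        eps *= 2.0**direction
    return eps


def sample_nuts(
    logp_grad,
    init: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics."""
    rng = np.random.default_rng(seed)
    q = np.asarray(init, dtype=float).copy()
    logp, g = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")
    inv_mass = np.ones(len(q))

    eps = _initial_step_size(rng, logp_grad, q, g, logp, inv_mass)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # warmup schedule: 15% step size, expanding variance windows, final 10%
    init_len = max(10, int(0.15 * n_warmup))
    term_len = max(10, int(0.10 * n_warmup))
    window_end = []
    w = 25
    pos = init_len
    while pos + w < n_warmup - term_len:
        pos += w
        window_end.append(pos)
        w *= 2
    if window_end:
        window_end[-1] = n_warmup - term_len
    buf = []

    draws = np.empty((n_draws, len(q)))
    accept_stat = np.empty(n_draws)
    tree_depth = np.empty(n_draws, dtype=int)
    divergences = 0

    da_iter = 0
    for i in range(n_warmup + n_draws):
        q, g, logp, accept, depth, div = _nuts_step(
            rng, logp_grad, q, g, logp, eps, inv_mass, max_treedepth
        )
        if i < n_warmup:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - accept) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            eta = da_iter**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if init_len <= i < (n_warmup - term_len):
                buf.append(q.copy())
            if window_end and i == window_end[0] - 1 and len(buf) > 4:
                var = np.var(np.asarray(buf), axis=0, ddof=1)
                n = len(buf)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                buf = []
                window_end.pop(0)
                # restart step-size adaptation for the new metric
                eps = _initial_step_size(rng, logp_grad, q, g, logp, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if i == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            j = i - n_warmup
            draws[j] = q
            accept_stat[j] = accept
            tree_depth[j] = depth
            divergences += int(div)

    return NutsResult(
        draws=draws,
        accept_stat=accept_stat,
        tree_depth=tree_depth,
        divergences=divergences,
        step_size=float(eps),
        inv_mass=inv_mass,
    )
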