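"""No-U-turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained dynamic Hamiltonian Monte Carlo implementation (multinomial
NUTS): trajectory doubling with the no-U-turn termination criterion,
multinomial sampling of the proposal within the trajectory, dual averaging of
the step size toward a target acceptance statistic during warmup, and
windowed Welford estimation of a diagonal mass matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_DELTA_H = 1000.0  # energy error beyond which a transition is divergent


@dataclass
class _Tree:
    z_minus: np.ndarray
    r_minus: np.ndarray
    g_minus: np.ndarray
    z_plus: np.ndarray
    r_plus: np.ndarray
    g_plus: np.ndarray
    z_prop: np.ndarray
    log_sum_weight: float
    sum_accept: float
    n_leaves: int
    diverged: bool
    turned: bool


def _logaddexp(a: float, b: float) -> float:
    return float(np.logaddexp(a, b))


class _Hamiltonian:
    def __init__(self, logp_grad, inv_mass: np.ndarray):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass

    def kinetic(self, r: np.ndarray) -> float:
        return 0.5 * float(np.dot(r * self.inv_mass, r))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.inv_mass.size) / np.sqrt(self.inv_mass)

    def leapfrog(self, z, r, grad, eps):
        r1 = r + 0.5 * eps * grad
        z1 = z + eps * self.inv_mass * r1
        lp, g1 = self.logp_grad(z1)
        r2 = r1 + 0.5 * eps * g1
        return z1, r2, g1, lp


def _uturn(ham: _Hamiltonian, z_minus, z_plus, r_minus, r_plus) -> bool:
    dz = z_plus - z_minus
    return (
        float(np.dot(dz, ham.inv_mass * r_minus)) < 0
        or float(np.dot(dz, ham.inv_mass * r_plus)) < 0
    )


def _build_tree(ham, z, r, grad, direction, depth, eps, h0, rng) -> _Tree:
    if depth == 0:
        z1, r1, g1, lp = ham.leapfrog(z, r, grad, direction * eps)
        h = -lp + ham.kinetic(r1) if np.isfinite(lp) else np.inf
        delta_h = h - h0
        diverged = not np.isfinite(h) or delta_h > _MAX_DELTA_H
        log_w = -delta_h if not diverged else -np.inf
        accept = float(np.exp(min(0.0, -delta_h))) if np.isfinite(delta_h) else 0.0
        return _Tree(z1, r1, g1, z1, r1, g1, z1, log_w, accept, 1, diverged, False)

    first = _build_tree(ham, z, r, grad, direction, depth - 1, eps, h0, rng)
    if first.diverged or first.turned:
        return first
    if direction == 1:
        second = _build_tree(
            ham, first.z_plus, first.r_plus, first.g_plus, direction, depth - 1, eps, h0, rng
        )
        z_minus, r_minus, g_minus = first.z_minus, first.r_minus, first.g_minus
        z_plus, r_plus, g_plus = second.z_plus, second.r_plus, second.g_plus
    else:
        second = _build_tree(
            ham, first.z_minus, first.r_minus, first.g_minus, direction, depth - 1, eps, h0, rng
        )
        z_minus, r_minus, g_minus = second.z_minus, second.r_minus, second.g_minus
        z_plus, r_plus, g_plus = first.z_plus, first.r_plus, first.g_plus
    log_w = _logaddexp(first.log_sum_weight, second.log_sum_weight)
    # multinomial sampling between subtrees
    if np.isfinite(second.log_sum_weight) and np.log(rng.uniform()) < second.log_sum_weight - log_w:
        z_prop = second.z_prop
    else:
        z_prop = first.z_prop
    turned = second.turned or _uturn(ham, z_minus, z_plus, r_minus, r_plus)
    return _Tree(
        z_minus, r_minus, g_minus, z_plus, r_plus, g_plus, z_prop,
        log_w, first.sum_accept + second.sum_accept,
        first.n_leaves + second.n_leaves, second.diverged, turned,
    )


def _nuts_transition(ham, z, eps, max_treedepth, rng):
    lp, grad = ham.logp_grad(z)
    r0 = ham.sample_momentum(rng)
    h0 = -lp + ham.kinetic(r0)
    z_minus = z_plus = z
    r_minus = r_plus = r0
    g_minus = g_plus = grad
    z_sample = z
    log_sum_weight = 0.0  # the initial point carries weight exp(-(h0-h0)) = 1
    sum_accept = 0.0
    n_leaves = 0
    diverged = False
    for depth in range(max_treedepth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            tree = _build_tree(ham, z_plus, r_plus, g_plus, 1, depth, eps, h0, rng)
            z_plus, r_plus, g_plus = tree.z_plus, tree.r_plus, tree.g_plus
        else:
            tree = _build_tree(ham, z_minus, r_minus, g_minus, -1, depth, eps, h0, rng)
            z_minus, r_minus, g_minus = tree.z_minus, tree.r_minus, tree.g_minus
        sum_accept += tree.sum_accept
        n_leaves += tree.n_leaves
        if tree.diverged:
            diverged = True
            break
        if tree.turned:
            break
        # progressive multinomial sampling against the accumulated trajectory
        new_total = _logaddexp(log_sum_weight, tree.log_sum_weight)
        if np.log(rng.uniform()) < tree.log_sum_weight - new_total:
            z_sample = tree.z_prop
        log_sum_weight = new_total
        if _uturn(ham, z_minus, z_plus, r_minus, r_plus):
            break
    accept_stat = sum_accept / max(n_leaves, 1)
    return z_sample, accept_stat, diverged


def _find_reasonable_epsilon(ham, z, rng) -> float:
    eps = 1.0
    lp, grad = ham.logp_grad(z)
    r = ham.sample_momentum(rng)
    h0 = -lp + ham.kinetic(r)
    _, r1, _, lp1 = ham.leapfrog(z, r, grad, eps)
    h1 = -lp1 + ham.kinetic(r1) if np.isfinite(lp1) else np.inf
    ratio = np.exp(h0 - h1) if np.isfinite(h1) else 0.0
    direction = 1.0 if ratio > 0.5 else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, _, lp1 = ham.leapfrog(z, r, grad, eps)
        h1 = -lp1 + ham.kinetic(r1) if np.isfinite(lp1) else np.inf
        ratio = np.exp(h0 - h1) if np.isfinite(h1) else 0.0
        if (direction == 1.0 and ratio <= 0.5) or (direction == -1.0 and ratio >= 0.5):
            break
    return float(np.clip(eps, 1e-8, 1e2))


class _DualAveraging:
    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit scale as Stan does
        w = self.n / (self.n + 5.0)
        return w * var + (1 - w) * 1e-3


def _adaptation_windows(n_warmup: int):
    """(start, end) index pairs of the mass-adaptation windows."""
    init = min(75, int(0.15 * n_warmup))
    term = min(50, int(0.10 * n_warmup))
    windows = []
    start = init
    size = 25
    end_of_adapt = n_warmup - term
    while start < end_of_adapt:
        end = min(start + size, end_of_adapt)
        if end_of_adapt - end < size:  # fold a too-small trailing window in
            end = end_of_adapt
        windows.append((start, end))
        start = end
        size *= 2
    return init, windows


def nuts_sample(
    logp_grad,
    z0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, dict]:
    """Run one NUTS chain; returns (draws, diagnostics).

    Warmup adapts the step size throughout and re-estimates a diagonal mass
    matrix over doubling windows; diagnostics report post-warmup divergences,
    the mean acceptance statistic and the adapted step size.
    """
    dim = z0.size
    inv_mass = np.ones(dim)
    ham = _Hamiltonian(logp_grad, inv_mass)
    eps = _find_reasonable_epsilon(ham, z0, rng)
    da = _DualAveraging(eps, target_accept)
    _, windows = _adaptation_windows(n_warmup)
    window_ends = {end: (start, end) for start, end in windows}
    welford = _Welford(dim)
    window_active = bool(windows)
    first_window_start = windows[0][0] if windows else n_warmup

    z = z0.copy()
    for i in range(n_warmup):
        z, accept_stat, _ = _nuts_transition(ham, z, eps, max_treedepth, rng)
        eps = da.update(accept_stat)
        if window_active and i >= first_window_start:
            welford.update(z)
        if window_active and (i + 1) in window_ends:
            var = welford.variance()
            ham.inv_mass = var
            welford = _Welford(dim)
            eps0 = da.adapted() if da.count else eps
            eps = eps0
            da = _DualAveraging(eps0, target_accept)
    eps = da.adapted() if n_warmup > 0 else eps

    draws = np.empty((n_samples, dim))
    divergences = 0
    accepts = []
    for i in range(n_samples):
        z, accept_stat, diverged = _nuts_transition(ham, z, eps, max_treedepth, rng)
        draws[i] = z
        divergences += int(diverged)
        accepts.append(accept_stat)
    diag = {
        "divergences": divergences,
        "mean_accept": float(np.mean(accepts)) if accepts else float("nan"),
        "step_size": float(eps),
    }
    return draws, diag
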