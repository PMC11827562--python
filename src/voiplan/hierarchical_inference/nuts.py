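"""A self-contained No-U-Turn sampler with Stan-style warmup adaptation.

Multinomial NUTS (progressive biased sampling) with dual-averaging step-size
adaptation and windowed diagonal mass-matrix estimation.  The implementation
is generic: it samples any callable ``logp_grad(q) -> (float, ndarray)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "NutsResult", "sample_nuts", "split_rhat"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_ENERGY_ERROR = 1000.0


@dataclass(frozen=True)
class NutsConfig:
    warmup: int = 500
    iterations: int = 1000  # total per chain, including warmup
    chains: int = 4
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8
    init_radius: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.warmup < self.iterations:
            raise ValueError("require 0 < warmup < iterations")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.warmup) * self.chains


@dataclass
class NutsResult:
    draws: np.ndarray  # (chains, kept, dim)
    logp: np.ndarray  # (chains, kept)
    treedepth: np.ndarray
    divergences: np.ndarray  # (chains, kept) bool
    accept_stat: np.ndarray
    step_size: np.ndarray  # (chains,)
    inv_mass: np.ndarray  # (chains, dim)
    n_divergent_warmup: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus", "q_plus", "p_plus", "grad_plus",
        "q_prop", "lp_prop", "grad_prop", "logw", "divergent", "turning",
        "accept_sum", "n_steps",
    )

    def __init__(self, q, p, grad, lp, logw, divergent, accept_sum, n_steps):
        self.q_minus = self.q_plus = self.q_prop = q
        self.p_minus = self.p_plus = p
        self.grad_minus = self.grad_plus = self.grad_prop = grad
        self.lp_prop = lp
        self.logw = logw
        self.divergent = divergent
        self.turning = False
        self.accept_sum = accept_sum
        self.n_steps = n_steps


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * inv_mass * p1
    lp1, grad1 = logp_grad(q1)
    p1 = p1 + 0.5 * eps * grad1
    return q1, p1, lp1, grad1


def _kinetic(p, inv_mass):
    with np.errstate(over="ignore"):
        return 0.5 * np.dot(p * p, inv_mass)


def _is_turning(q_minus, q_plus, p_minus, p_plus, inv_mass):
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _build_tree(logp_grad, q, p, grad, depth, direction, eps, h0, inv_mass, rng):
    if depth == 0:
        q1, p1, lp1, grad1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        dh = h1 - h0
        divergent = (not np.isfinite(dh)) or dh < -_MAX_ENERGY_ERROR
        logw = -np.inf if divergent else dh
        accept = 0.0 if not np.isfinite(dh) else min(1.0, float(np.exp(min(dh, 0.0))))
        return _Tree(q1, p1, grad1, lp1, logw, divergent, accept, 1)

    inner = _build_tree(logp_grad, q, p, grad, depth - 1, direction, eps, h0, inv_mass, rng)
    if inner.divergent or inner.turning:
        return inner
    if direction == 1:
        outer = _build_tree(
            logp_grad, inner.q_plus, inner.p_plus, inner.grad_plus,
            depth - 1, direction, eps, h0, inv_mass, rng,
        )
        inner.q_plus, inner.p_plus, inner.grad_plus = outer.q_plus, outer.p_plus, outer.grad_plus
    else:
        outer = _build_tree(
            logp_grad, inner.q_minus, inner.p_minus, inner.grad_minus,
            depth - 1, direction, eps, h0, inv_mass, rng,
        )
        inner.q_minus, inner.p_minus, inner.grad_minus = outer.q_minus, outer.p_minus, outer.grad_minus

    total = np.logaddexp(inner.logw, outer.logw)
    if np.isfinite(outer.logw) and np.log(rng.uniform()) < outer.logw - total:
        inner.q_prop, inner.lp_prop, inner.grad_prop = (
            outer.q_prop, outer.lp_prop, outer.grad_prop,
        )
    inner.logw = total
    inner.accept_sum += outer.accept_sum
    inner.n_steps += outer.n_steps
    inner.divergent = outer.divergent
    inner.turning = outer.turning or _is_turning(
        inner.q_minus, inner.q_plus, inner.p_minus, inner.p_plus, inv_mass
    )
    return inner


def _transition(logp_grad, q, lp, grad, eps, inv_mass, max_depth, rng):
    """One NUTS draw: returns (q, lp, grad, depth, divergent, accept_stat)."""
    p0 = rng.normal(size=q.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p0, inv_mass)

    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    q_prop, lp_prop, grad_prop = q, lp, grad
    logw_total = 0.0
    accept_sum, n_steps = 0.0, 0
    divergent = False
    depth = 0

    for depth in range(1, max_depth + 1):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(
                logp_grad, q_plus, p_plus, grad_plus, depth - 1, 1, eps, h0, inv_mass, rng
            )
            q_plus, p_plus, grad_plus = sub.q_plus, sub.p_plus, sub.grad_plus
        else:
            sub = _build_tree(
                logp_grad, q_minus, p_minus, grad_minus, depth - 1, -1, eps, h0, inv_mass, rng
            )
            q_minus, p_minus, grad_minus = sub.q_minus, sub.p_minus, sub.grad_minus

        accept_sum += sub.accept_sum
        n_steps += sub.n_steps
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.uniform()) < sub.logw - logw_total:
            q_prop, lp_prop, grad_prop = sub.q_prop, sub.lp_prop, sub.grad_prop
        logw_total = np.logaddexp(logw_total, sub.logw)
        if _is_turning(q_minus, q_plus, p_minus, p_plus, inv_mass):
            break

    accept_stat = accept_sum / max(n_steps, 1)
    return q_prop, lp_prop, grad_prop, depth, divergent, accept_stat


def _find_reasonable_epsilon(logp_grad, q, lp, grad, inv_mass, rng):
    eps = 1.0
    p = rng.normal(size=q.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    dh = (lp1 - _kinetic(p1, inv_mass)) - h0
    if not np.isfinite(dh):
        dh = -np.inf
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        dh = (lp1 - _kinetic(p1, inv_mass)) - h0
        if not np.isfinite(dh):
            dh = -np.inf
        if direction * dh <= direction * np.log(0.5):
            break
    return eps


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) covariance-estimation windows within warmup, Stan style."""
    if n_warmup < 20:
        return []
    if n_warmup < 150:
        init_buf = max(1, int(0.15 * n_warmup))
        term_buf = max(1, int(0.10 * n_warmup))
        base = n_warmup - init_buf - term_buf
        return [(init_buf, init_buf + base)] if base >= 10 else []
    init_buf, term_buf, base = 75, 50, 25
    windows = []
    start = init_buf
    size = base
    while True:
        end = start + size
        if end + 2 * size > n_warmup - term_buf:
            end = n_warmup - term_buf
            windows.append((start, end))
            break
        windows.append((start, end))
        start = end
        size *= 2
    return windows


class _DualAveraging:
    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def restart(self, eps0: float) -> None:
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _run_chain(logp_grad, q0, cfg: NutsConfig, rng):
    dim = q0.size
    kept = cfg.iterations - cfg.warmup
    draws = np.empty((kept, dim))
    lps = np.empty(kept)
    depths = np.zeros(kept, dtype=np.int64)
    divs = np.zeros(kept, dtype=bool)
    accepts = np.empty(kept)

    inv_mass = np.ones(dim)
    q = q0.copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log density at the initial point")

    eps = _find_reasonable_epsilon(logp_grad, q, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, cfg.target_accept)
    windows = _adaptation_windows(cfg.warmup)
    window_samples: list[np.ndarray] = []
    n_div_warmup = 0

    for it in range(cfg.iterations):
        q, lp, grad, depth, divergent, accept = _transition(
            logp_grad, q, lp, grad, eps, inv_mass, cfg.max_treedepth, rng
        )
        if it < cfg.warmup:
            eps = da.update(accept)
            n_div_warmup += int(divergent)
            for start, end in windows:
                if start <= it < end:
                    window_samples.append(q.copy())
                if it == end - 1 and window_samples:
                    samp = np.asarray(window_samples)
                    n = samp.shape[0]
                    var = samp.var(axis=0, ddof=1) if n > 1 else np.ones(dim)
                    w = n / (n + 5.0)
                    inv_mass = w * var + (1 - w) * 1.0
                    window_samples = []
                    eps = _find_reasonable_epsilon(logp_grad, q, lp, grad, inv_mass, rng)
                    da.restart(eps)
            if it == cfg.warmup - 1:
                eps = da.adapted
        else:
            k = it - cfg.warmup
            draws[k] = q
            lps[k] = lp
            depths[k] = depth
            divs[k] = divergent
            accepts[k] = accept

    return draws, lps, depths, divs, accepts, eps, inv_mass, n_div_warmup


def sample_nuts(
    logp_grad: LogpGrad,
    dim: int,
    cfg: NutsConfig,
    init: np.ndarray | None = None,
) -> NutsResult:
    """Run ``cfg.chains`` sequential NUTS chains and return retained draws."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    kept = cfg.iterations - cfg.warmup
    draws = np.empty((cfg.chains, kept, dim))
    lps = np.empty((cfg.chains, kept))
    depths = np.empty((cfg.chains, kept), dtype=np.int64)
    divs = np.empty((cfg.chains, kept), dtype=bool)
    accepts = np.empty((cfg.chains, kept))
    step_sizes = np.empty(cfg.chains)
    inv_masses = np.empty((cfg.chains, dim))
    n_div_w = 0

    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        q0 = (
            init.copy()
            if init is not None
            else rng.uniform(-cfg.init_radius, cfg.init_radius, size=dim)
        )
        if init is not None:
            q0 = q0 + rng.uniform(-0.1, 0.1, size=dim)
        out = _run_chain(logp_grad, q0, cfg, rng)
        draws[c], lps[c], depths[c], divs[c], accepts[c], step_sizes[c], inv_masses[c], ndw = out
        n_div_w += ndw

    return NutsResult(
        draws=draws,
        logp=lps,
        treedepth=depths,
        divergences=divs,
        accept_stat=accepts,
        step_size=step_sizes,
        inv_mass=inv_masses,
        n_divergent_warmup=n_div_w,
    )


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for draws shaped (chains, draws)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
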