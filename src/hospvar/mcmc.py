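"""Self-contained Hamiltonian Monte Carlo with warmup adaptation.

A compact, dependency-free sampler for smooth, moderate-dimension posteriors:
leapfrog HMC with jittered trajectory length, dual-averaging step-size
adaptation and a diagonal mass matrix estimated from late-warmup draws.  The
transition is a standard Metropolis-corrected HMC step, so the chain is
asymptotically exact for the supplied log density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_leapfrog: int = 32
    init_step: float = 0.1
    jitter: float = 1.0  # chain-init spread around the supplied start point


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, step0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.h_bar = 0.0
        self.log_step_bar = np.log(step0)
        self.count = 0
        self.log_step = np.log(step0)

    def update(self, accept_prob):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_step = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_step_bar = eta * self.log_step + (1 - eta) * self.log_step_bar

    @property
    def step(self):
        return float(np.exp(self.log_step))

    @property
    def adapted_step(self):
        return float(np.exp(self.log_step_bar))


def _leapfrog(grad, x, p, step, n_steps, inv_mass, logp_and_grad):
    lp, g = None, grad
    p = p + 0.5 * step * g
    for i in range(n_steps):
        x = x + step * inv_mass * p
        lp, g = logp_and_grad(x)
        if not np.all(np.isfinite(g)):
            return x, p, -np.inf, g
        if i < n_steps - 1:
            p = p + step * g
    p = p + 0.5 * step * g
    return x, p, lp, g


def _hmc_step(logp_and_grad, x, lp, g, step, inv_mass, rng, max_leapfrog):
    dim = x.size
    p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
    n_steps = int(rng.integers(1, max_leapfrog + 1))
    h0 = lp - 0.5 * np.sum(inv_mass * p0 ** 2)
    x1, p1, lp1, g1 = _leapfrog(g, x, p0, step, n_steps, inv_mass, logp_and_grad)
    if not np.isfinite(lp1):
        return x, lp, g, 0.0, False
    with np.errstate(over="ignore"):
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
    log_ratio = h1 - h0
    if log_ratio < -1000.0:  # divergence guard
        return x, lp, g, 0.0, False
    accept_prob = float(min(1.0, np.exp(min(0.0, log_ratio))))
    if rng.random() < accept_prob:
        return x1, lp1, g1, accept_prob, True
    return x, lp, g, accept_prob, False


def run_chain(logp_and_grad, x0, config: SamplerConfig, rng) -> dict:
    """Run one HMC chain; returns draws plus acceptance statistics.

    Warmup schedule: 40% step-size adaptation under unit mass, 50% continued
    adaptation while collecting draws for the diagonal mass estimate, final
    10% step-size re-adaptation under the new metric.
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    inv_mass = np.ones(dim)
    lp, g = logp_and_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    da = _DualAveraging(config.init_step, target=config.target_accept)
    w1 = int(0.4 * config.warmup)
    w2 = int(0.9 * config.warmup)
    mass_window = []
    n_accept = 0

    for i in range(config.warmup):
        step = da.step
        x, lp, g, aprob, accepted = _hmc_step(
            logp_and_grad, x, lp, g, step, inv_mass, rng, config.max_leapfrog)
        da.update(aprob)
        if w1 <= i < w2:
            mass_window.append(x.copy())
        if i == w2 - 1 and len(mass_window) >= 10:
            var = np.var(np.asarray(mass_window), axis=0)
            inv_mass = np.clip(var, 1e-8, None)
            da = _DualAveraging(da.adapted_step, target=config.target_accept)

    step = da.adapted_step
    draws = np.empty((config.draws, dim))
    for i in range(config.draws):
        x, lp, g, aprob, accepted = _hmc_step(
            logp_and_grad, x, lp, g, step, inv_mass, rng, config.max_leapfrog)
        n_accept += accepted
        draws[i] = x
    return {
        "draws": draws,
        "accept_rate": n_accept / config.draws,
        "step_size": step,
        "inv_mass": inv_mass,
    }


def sample(logp_and_grad, x0, config: SamplerConfig, seed: int) -> dict:
    """Run ``config.chains`` independent chains; returns stacked draws of
    shape (chains, draws, dim) plus per-chain stats."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(config.chains)
    all_draws, stats = [], []
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        start = np.asarray(x0, dtype=float) + config.jitter * rng.normal(size=len(x0))
        res = run_chain(logp_and_grad, start, config, rng)
        all_draws.append(res["draws"])
        stats.append({k: res[k] for k in ("accept_rate", "step_size")})
    return {"draws": np.stack(all_draws), "chains": stats}
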