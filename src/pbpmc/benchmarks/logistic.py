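"""Tau-leaping logistic birth-death population model.

Time is discretized in steps of size tau.  With population P_t, births and
deaths in step t are Poisson,

    b_t ~ Pois(tau * r_b * P_t * (1 - P_t / K))   (mean clamped at 0),
    d_t ~ Pois(tau * mu * P_t),
    P_{t+1} = P_t + b_t - d_t,

with birth rate r_b, mortality rate mu and carrying capacity K.  Trap
counts y_m ~ Binomial(P_{t_m}, p) are recorded at M measurement times with
capture probability p.  Trajectories that drive P_t negative get zero
likelihood rather than being blocked at proposal time.

The population sizes are deterministic given the births and deaths, so the
latent state is the (b_t, d_t) sequence; P_t is a computed field.  Because
each trap count is informed by *future* as well as past latent variables,
the simple data-folding importance distributions do not apply here and the
recommended scheme is ID0 (model-based proposals).  The data alone cannot
pin down all four parameters, so semi-informative priors are placed on
mortality and capture probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from ..dag import DagModel, LatentNode, ObsTerm, ParamSpec
from ..importance import make_id0

__all__ = ["LogisticScenario", "build_logistic"]


@dataclass
class LogisticScenario:
    """Generating scenario; T time points give T-1 tau-leap steps."""

    T: int = 401
    tau: float = 0.1
    r_b: float = 0.6
    mu: float = 0.3
    K: float = 100.0
    p: float = 0.5
    M: int = 21
    P0: int = 5

    def __post_init__(self):
        if self.tau <= 0 or self.K <= 0:
            raise ValueError("tau and K must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @property
    def measure_times(self) -> np.ndarray:
        return np.linspace(0, self.T - 1, self.M).round().astype(int)

    def simulate(self, rng: np.random.Generator) -> dict:
        steps = self.T - 1
        b = np.zeros(steps, dtype=int)
        d = np.zeros(steps, dtype=int)
        pop = np.zeros(self.T, dtype=int)
        pop[0] = self.P0
        for t in range(steps):
            lam_b = max(0.0, self.tau * self.r_b * pop[t] * (1 - pop[t] / self.K))
            b[t] = rng.poisson(lam_b)
            d[t] = rng.poisson(self.tau * self.mu * pop[t])
            pop[t + 1] = pop[t] + b[t] - d[t]
            if pop[t + 1] < 0:           # resample the step: data generation
                pop[t + 1] = 0           # only, keep trajectories feasible
                d[t] = pop[t] + b[t]
        tm = self.measure_times
        y = rng.binomial(pop[tm], self.p)
        data = pd.DataFrame({"time": tm, "trap_count": y})
        truth = pd.DataFrame({"time": np.arange(self.T), "P": pop,
                              "b": np.append(b, 0), "d": np.append(d, 0)})
        return {"data": data, "latent_truth": truth}


@njit(cache=True)
def _pois_logpmf(k, lam):
    if k < 0:
        return -np.inf
    if lam <= 0.0:
        return 0.0 if k == 0 else -np.inf
    return k * math.log(lam) - lam - math.lgamma(k + 1.0)


@njit(cache=True)
def _pois_kernel(lam_i, lam_p, k):
    if lam_p > lam_i:
        return k + np.random.poisson(lam_p - lam_i)
    if lam_i <= 0.0:
        return k
    ratio = lam_p / lam_i
    if ratio >= 1.0:
        return k
    return np.random.binomial(k, ratio)


@njit(cache=True)
def _logi_pbp_sweep(xi_i, th_i, th_p, tau, p0, seed):
    """Sequential ID0 sweep over (b_t, d_t); xi stores [b_0, d_0, b_1, ...]."""
    np.random.seed(seed)
    steps = xi_i.shape[0] // 2
    xi_p = np.empty(xi_i.shape[0])
    pop_i = p0
    pop_p = p0
    log_corr = 0.0
    for t in range(steps):
        lb_i = max(0.0, tau * th_i[0] * pop_i * (1.0 - pop_i / th_i[2]))
        lb_p = max(0.0, tau * th_p[0] * pop_p * (1.0 - pop_p / th_p[2]))
        ld_i = tau * th_i[1] * pop_i
        ld_p = tau * th_p[1] * pop_p
        b_i = int(xi_i[2 * t])
        d_i = int(xi_i[2 * t + 1])
        b_p = _pois_kernel(lb_i, lb_p, b_i)
        d_p = _pois_kernel(ld_i, ld_p, d_i)
        xi_p[2 * t] = b_p
        xi_p[2 * t + 1] = d_p
        log_corr += _pois_logpmf(b_i, lb_i) + _pois_logpmf(d_i, ld_i)
        log_corr -= _pois_logpmf(b_p, lb_p) + _pois_logpmf(d_p, ld_p)
        pop_i += b_i - d_i
        pop_p += b_p - d_p
        if pop_p < 0:
            return xi_p, -np.inf
    return xi_p, log_corr


@njit(cache=True)
def _logi_suffix_loglik(xi, th, tau, p0, t_from, mtimes, yobs):
    """Latent + observation log likelihood restricted to steps >= t_from."""
    steps = xi.shape[0] // 2
    pop = p0
    for t in range(t_from):
        pop += int(xi[2 * t]) - int(xi[2 * t + 1])
    total = 0.0
    m = 0
    while m < mtimes.shape[0] and mtimes[m] < t_from:
        m += 1
    for t in range(t_from, steps + 1):
        if pop < 0:
            return -np.inf
        while m < mtimes.shape[0] and mtimes[m] == t:
            y = yobs[m]
            if y > pop:
                return -np.inf
            total += (math.lgamma(pop + 1.0) - math.lgamma(y + 1.0)
                      - math.lgamma(pop - y + 1.0)
                      + y * math.log(th[3]) + (pop - y) * math.log(1 - th[3]))
            m += 1
        if t == steps:
            break
        lb = max(0.0, tau * th[0] * pop * (1.0 - pop / th[2]))
        ld = tau * th[1] * pop
        total += _pois_logpmf(int(xi[2 * t]), lb)
        total += _pois_logpmf(int(xi[2 * t + 1]), ld)
        pop += int(xi[2 * t]) - int(xi[2 * t + 1])
    return total


@njit(cache=True)
def _logi_latent_sweep(xi, th, tau, p0, mtimes, yobs, seed, step):
    np.random.seed(seed)
    n = xi.shape[0]
    n_acc = 0
    width = max(1, int(step))
    for idx in range(n):
        t = idx // 2
        old = xi[idx]
        move = 1 + np.random.randint(0, width)
        if np.random.random() < 0.5:
            move = -move
        new = old + move
        if new < 0:
            continue
        before = _logi_suffix_loglik(xi, th, tau, p0, t, mtimes, yobs)
        xi[idx] = new
        after = _logi_suffix_loglik(xi, th, tau, p0, t, mtimes, yobs)
        delta = after - before
        if delta >= 0.0 or math.log(np.random.random()) < delta:
            n_acc += 1
        else:
            xi[idx] = old
    return xi, n_acc, n


class _LogisticPlan:
    def __init__(self, tau, p0, mtimes, yobs):
        self.tau = float(tau)
        self.p0 = int(p0)
        self.mtimes = np.asarray(mtimes, dtype=np.int64)
        self.yobs = np.asarray(yobs, dtype=np.int64)

    def logliks(self, theta, xi):
        th = np.asarray(theta, dtype=float)
        if not (0.0 < th[3] < 1.0):
            return -np.inf, 0.0
        total = _logi_suffix_loglik(xi, th, self.tau, self.p0, 0,
                                    self.mtimes, self.yobs)
        # suffix loglik mixes latent+obs; report it as latent, 0 as obs
        return float(total), 0.0

    def pbp_sweep(self, level, xi, theta_i, theta_p, seed, kappa):
        xi_p, log_corr = _logi_pbp_sweep(xi, np.asarray(theta_i, float),
                                         np.asarray(theta_p, float),
                                         self.tau, self.p0, seed)
        if not np.isfinite(log_corr):
            return None
        return xi_p, float(log_corr)

    def latent_sweep(self, xi, theta, seed, lstep):
        out, n_acc, n_tot = _logi_latent_sweep(
            xi.copy(), np.asarray(theta, float), self.tau, self.p0,
            self.mtimes, self.yobs, seed, lstep)
        return out, n_acc, n_tot


def build_logistic(scn: LogisticScenario, data: pd.DataFrame = None,
                   rng: np.random.Generator = None):
    """Build the tau-leaping model with ID0 (model-based proposals)."""
    if data is None:
        if rng is None:
            raise ValueError("need data or an rng to simulate it")
        data = scn.simulate(rng)["data"]
    mtimes = data["time"].to_numpy().astype(int)
    yobs = data["trap_count"].to_numpy().astype(int)
    steps = scn.T - 1
    tau, p0 = scn.tau, scn.P0

    # semi-informative priors on mortality and capture probability
    mu_shape, mu_rate = 16.0, 16.0 / 0.3          # mean 0.3, CV 0.25
    p_a, p_b = 10.0, 10.0                         # mean 0.5, ESS 20
    params = [
        ParamSpec("r_b", 0.0, 5.0, sample_init=lambda r: r.uniform(0.2, 1.5)),
        ParamSpec("mu", 0.0, 5.0,
                  log_prior=lambda v: stats.gamma.logpdf(v, mu_shape,
                                                         scale=1 / mu_rate),
                  sample_init=lambda r: r.gamma(mu_shape, 1 / mu_rate)),
        ParamSpec("K", 1.0, 2000.0,
                  sample_init=lambda r: r.uniform(20.0, 400.0)),
        ParamSpec("p", 0.0, 1.0,
                  log_prior=lambda v: stats.beta.logpdf(v, p_a, p_b),
                  sample_init=lambda r: r.beta(p_a, p_b)),
    ]

    def pop_at(xi, t):
        pop = p0
        for s in range(t):
            pop += int(xi[2 * s]) - int(xi[2 * s + 1])
        return pop

    def birth_node(t):
        def cond(xi, th):
            pop = pop_at(xi, t)
            if pop < 0:
                raise ValueError("negative population")
            return {"lam": max(0.0, tau * th[0] * pop * (1 - pop / th[2]))}
        return LatentNode("poisson", cond, parents=tuple(range(2 * t)))

    def death_node(t):
        def cond(xi, th):
            pop = pop_at(xi, t)
            if pop < 0:
                raise ValueError("negative population")
            return {"lam": tau * th[1] * pop}
        return LatentNode("poisson", cond, parents=tuple(range(2 * t)))

    nodes = []
    for t in range(steps):
        nodes.append(birth_node(t))
        nodes.append(death_node(t))

    def obs_logp(tm):
        def logp(xi, th, y):
            pop = pop_at(xi, tm)
            if pop < 0 or y > pop:
                return -np.inf
            return float(stats.binom.logpmf(y, pop, th[3]))
        return logp

    def obs_sample(tm):
        def sample(xi, th, r):
            pop = pop_at(xi, tm)
            return int(r.binomial(max(pop, 0), th[3]))
        return sample

    obs = [ObsTerm(tuple(range(min(2 * tm, 2 * steps))), obs_logp(tm),
                   obs_sample(tm), int(y))
           for tm, y in zip(mtimes, yobs)]
    model = DagModel(params, nodes, obs, name="logistic")
    plan = _LogisticPlan(tau, p0, mtimes, yobs)
    model.fast_plans = {0: plan, "baseline": plan}
    return model, make_id0(model)
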