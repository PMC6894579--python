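"""Adaptive MCMC engine: posterior-based proposals interleaved with
standard single-site updates.

One PBP update proposes all parameters jointly from a multivariate normal
random walk, regenerates every latent variable through the
marginal-preserving kernels (initial vs proposed importance-distribution
parameters), and accepts or rejects the whole move with a single
Metropolis–Hastings probability.  Because the kernels satisfy the
marginal-preservation condition, the proposal density itself never appears
in the ratio — only the importance-distribution densities at the initial
and proposed states do.

Every ``interleave``-th update is a standard sweep (single-site
random-walk/Gibbs moves on each latent, then each parameter) which breaks
the residual correlation a PBP leaves between successive latent states.
During burn-in the proposal covariance, the jump scale j (targeting a fixed
PBP acceptance rate) and the single-site step sizes are adapted; adaptation
is frozen afterwards so the sampling phase is a valid Markov chain.

Benchmark models may attach a *fast plan* — vectorized or jit-compiled
implementations of the latent sweeps and likelihood evaluations with the
same semantics as the generic path; the engine uses one when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import kernels
from .dag import ChainState, DagModel
from .importance import IdSpec

__all__ = [
    "EngineConfig",
    "AdaptState",
    "Trace",
    "propose_theta",
    "pbp_update",
    "standard_update",
    "adapt",
    "run_chain",
]


@dataclass
class EngineConfig:
    """Run configuration.

    ``updates`` counts post-burn-in updates; ``interleave`` is the block
    size U: each block holds U-1 PBP updates and one standard sweep.
    """

    updates: int = 10_000
    burnin: int = 2_000
    interleave: int = 4
    jump: Optional[float] = None   # default 2.38 / sqrt(n_params)
    target_accept: float = 0.33
    kappa: float = 0.03
    adapt_window: int = 50
    store_latent: int = 0     # keep a latent snapshot every k-th update (0=off)
    seed: int = 0

    def __post_init__(self):
        if self.interleave < 1:
            raise ValueError("interleave must be a positive integer")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.jump is not None and self.jump <= 0:
            raise ValueError("jump must be positive")


@dataclass
class AdaptState:
    """Adapted quantities: proposal covariance, jump scale, step sizes."""

    sigma: np.ndarray
    j: float
    lstep: float = 1.0
    psteps: np.ndarray = None
    chol: np.ndarray = None
    frozen: bool = False
    block_acc: int = 0     # stage-2 fixed-j measurement block
    block_tot: int = 0
    block_k: int = 0

    def __post_init__(self):
        if self.psteps is None:
            self.psteps = np.ones(len(self.sigma))
        self.refresh_chol()

    def refresh_chol(self):
        sig = np.atleast_2d(self.sigma)
        jitter = 1e-12 * max(1.0, float(np.max(np.diag(sig))))
        for _ in range(8):
            try:
                self.chol = np.linalg.cholesky(
                    sig + jitter * np.eye(len(sig))
                )
                return
            except np.linalg.LinAlgError:
                jitter *= 10.0
        raise np.linalg.LinAlgError("proposal covariance not positive definite")


def propose_theta(theta: np.ndarray, chol: np.ndarray, j: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Multivariate-normal random-walk draw with covariance j^2 * Sigma."""
    return theta + j * (chol @ rng.standard_normal(len(theta)))


def adapt(state: AdaptState, window_thetas: np.ndarray,
          observed_accept: float, target: float, c: float = 0.1) -> AdaptState:
    """One adaptation step: shrinkage covariance estimate + jump-scale control.

    The jump scale moves by a factor exp(c*(observed - target)), clamped to
    [0.02, 10]; the covariance is the windowed sample covariance shrunk 10%
    toward its diagonal.  No-op when the state is frozen.
    """
    if state.frozen:
        return state
    n, d = np.atleast_2d(window_thetas).shape
    if n >= max(10, 2 * d):
        s = np.cov(np.atleast_2d(window_thetas).T, ddof=1)
        s = np.atleast_2d(s)
        if np.all(np.isfinite(s)) and np.any(np.diag(s) > 0):
            shrunk = 0.9 * s + 0.1 * np.diag(np.diag(s))
            shrunk += 1e-10 * max(1.0, np.max(np.diag(s))) * np.eye(d)
            state.sigma = shrunk
            state.refresh_chol()
    state.j = float(np.clip(state.j * math.exp(c * (observed_accept - target)),
                            0.02, 10.0))
    return state


@dataclass
class Trace:
    """Posterior samples of theta plus acceptance bookkeeping."""

    param_names: list
    thetas: np.ndarray
    logpost: np.ndarray
    is_pbp: np.ndarray
    accepted: np.ndarray
    counters: dict = field(default_factory=dict)
    latents: list = field(default_factory=list)
    j_final: float = float("nan")
    sigma_final: Optional[np.ndarray] = None

    def __len__(self):
        return len(self.thetas)

    def param(self, name: str) -> np.ndarray:
        return self.thetas[:, self.param_names.index(name)]

    def acceptance(self, kind: str = "pbp") -> float:
        acc, tot = self.counters.get(kind, (0, 0))
        return acc / tot if tot else float("nan")

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.thetas, columns=self.param_names)
        df.insert(0, "update", np.arange(len(df)))
        df["log_posterior"] = self.logpost
        df["is_pbp"] = self.is_pbp.astype(int)
        df["accepted"] = self.accepted.astype(int)
        return df


# ---------------------------------------------------------------------------
# single updates (generic path)
# ---------------------------------------------------------------------------


def pbp_update(state: ChainState, model: DagModel, ids: IdSpec,
               adapt_state: AdaptState, cfg: EngineConfig,
               rng: np.random.Generator, loglik=None):
    """One joint PBP update.

    Returns (state, accepted, info) where info carries the proposal and the
    pieces of the acceptance ratio (log_alpha, log_corr, proposed state and
    its likelihood components) for logging and verification.
    """
    theta_i = state.theta
    u_p = propose_theta(model.theta_to_u(theta_i), adapt_state.chol,
                        adapt_state.j, rng)
    theta_p = model.theta_from_u(u_p)
    prior_p = model.prior_loglik(theta_p)
    if prior_p == -np.inf:
        return state, False, {"log_alpha": -np.inf, "reason": "prior"}
    # Hastings term for proposing in transformed coordinates
    log_jac = (model.proposal_log_jacobian(theta_i)
               - model.proposal_log_jacobian(theta_p))
    kcfg = kernels.KernelConfig(cfg.kappa)
    xi_p = state.xi.copy()
    log_corr = 0.0
    try:
        for e in range(model.n_nodes):
            fam = ids.families[e]
            params_i = ids.params(e, state.xi, theta_i)
            params_p = ids.params(e, xi_p, theta_p)
            xi_p[e] = kernels.propose(fam, params_i, params_p, state.xi[e],
                                      rng, kcfg)
            log_corr += float(kernels.log_density(fam, params_i, state.xi[e]))
            log_corr -= float(kernels.log_density(fam, params_p, xi_p[e]))
    except (ValueError, FloatingPointError, NotImplementedError):
        return state, False, {"log_alpha": -np.inf, "reason": "invalid-id"}
    if not np.isfinite(log_corr):
        return state, False, {"log_alpha": -np.inf, "reason": "correction"}
    if loglik is None:
        lat_p = model.latent_loglik(theta_p, xi_p)
        obs_p = model.obs_loglik(theta_p, xi_p)
    else:
        lat_p, obs_p = loglik(theta_p, xi_p)
    log_alpha = ((lat_p + obs_p + prior_p)
                 - (state.lat_ll + state.obs_ll + state.prior_ll)
                 + log_corr + log_jac)
    info = {"log_alpha": log_alpha, "log_corr": log_corr,
            "log_jac": log_jac, "theta_p": theta_p, "xi_p": xi_p,
            "lat_p": lat_p, "obs_p": obs_p, "prior_p": prior_p}
    if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
        return ChainState(theta_p, xi_p, lat_p, obs_p, prior_p), True, info
    return state, False, info


def _latent_proposal(model, e, x, lstep, rng):
    fam = model.nodes[e].family
    if fam == "bernoulli":
        return 1.0 - x
    if fam in ("poisson", "binomial", "geometric", "negative_binomial"):
        return x + (1 if rng.random() < 0.5 else -1) * (
            1 + rng.integers(0, max(1, int(lstep)))
        )
    return x + lstep * rng.standard_normal()


def standard_update(state: ChainState, model: DagModel,
                    rng: np.random.Generator, adapt_state: AdaptState,
                    loglik=None):
    """One standard sweep: every latent, then every parameter, single-site.

    Latents move by Metropolis (bit-flip for Bernoulli, +/- steps for count
    families, Gaussian steps otherwise) using local delta evaluation;
    parameters move by random-walk Metropolis, or a registered conjugate
    Gibbs draw.  The latent scan order is re-randomized each sweep, which
    makes the sweep kernel reversible (a uniformly drawn permutation is
    distributed like its reverse).  Returns (state, latent acc/tot,
    parameter acc/tot).
    """
    lat_acc = lat_tot = 0
    for e in rng.permutation(model.n_nodes):
        new = _latent_proposal(model, e, state.xi[e], adapt_state.lstep, rng)
        d_lat, d_obs = model.delta_components(state, e, new)
        lat_tot += 1
        delta = d_lat + d_obs
        if delta >= 0 or math.log(rng.random()) < delta:
            state.xi[e] = new
            state.lat_ll += d_lat
            state.obs_ll += d_obs
            lat_acc += 1
    par_acc = par_tot = 0
    gibbs_done = False
    for k, spec in enumerate(model.params):
        gibbs = model.param_gibbs.get(spec.name)
        if gibbs is not None:
            state.theta[k] = gibbs(state.xi, state.theta, rng)
            gibbs_done = True
            par_acc += 1
            par_tot += 1
            continue
        if gibbs_done:
            _refresh(state, model, loglik)
            gibbs_done = False
        theta_p = state.theta.copy()
        theta_p[k] += adapt_state.psteps[k] * rng.standard_normal()
        prior_p = model.prior_loglik(theta_p)
        par_tot += 1
        if prior_p == -np.inf:
            continue
        if loglik is None:
            lat_p = model.latent_loglik(theta_p, state.xi)
            obs_p = model.obs_loglik(theta_p, state.xi)
        else:
            lat_p, obs_p = loglik(theta_p, state.xi)
        delta = (lat_p + obs_p + prior_p
                 - state.lat_ll - state.obs_ll - state.prior_ll)
        if delta >= 0 or math.log(rng.random()) < delta:
            state.theta = theta_p
            state.lat_ll, state.obs_ll, state.prior_ll = lat_p, obs_p, prior_p
            par_acc += 1
    if gibbs_done:
        _refresh(state, model, loglik)
    return state, (lat_acc, lat_tot), (par_acc, par_tot)


def _refresh(state, model, loglik):
    if loglik is None:
        state.lat_ll = model.latent_loglik(state.theta, state.xi)
        state.obs_ll = model.obs_loglik(state.theta, state.xi)
    else:
        state.lat_ll, state.obs_ll = loglik(state.theta, state.xi)
    state.prior_ll = model.prior_loglik(state.theta)


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------


def _init_state(model, cfg, rng, init_theta, init_xi, loglik):
    for attempt in range(100):
        if init_theta is not None:
            theta = np.asarray(init_theta, dtype=float).copy()
        else:
            theta = np.array([spec.draw_init(rng) for spec in model.params])
        if init_xi is not None:
            xi = np.asarray(init_xi, dtype=float).copy()
        else:
            try:
                xi, _ = model.simulate_forward(theta, rng)
            except ValueError:
                continue
        if loglik is None:
            lat = model.latent_loglik(theta, xi)
            obs = model.obs_loglik(theta, xi)
        else:
            lat, obs = loglik(theta, xi)
        prior = model.prior_loglik(theta)
        if np.isfinite(lat + obs + prior):
            return ChainState(np.asarray(theta, float), np.asarray(xi, float),
                              lat, obs, prior)
        if init_theta is not None and init_xi is not None:
            break
    raise RuntimeError(
        "could not find a feasible initial state in 100 attempts; supply "
        "init_theta/init_xi with finite posterior density"
    )


def run_chain(model: DagModel, ids: Optional[IdSpec], cfg: EngineConfig,
              rng: Optional[np.random.Generator] = None, *,
              init_theta=None, init_xi=None, sigma0=None,
              adapt_enabled: bool = True, use_fast: bool = True) -> Trace:
    """Run burn-in/adaptation then the sampling phase; return a Trace.

    With ``ids`` given, each block of ``cfg.interleave`` updates holds
    interleave-1 PBP updates and one standard sweep; with ``ids=None`` the
    chain is the pure standard (baseline) sampler.  Fixed seeds give
    bit-identical traces.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    plan = None
    if use_fast:
        key = ids.level if ids is not None else "baseline"
        plan = model.fast_plans.get(key)
    loglik = plan.logliks if plan is not None else None

    state = _init_state(model, cfg, rng, init_theta, init_xi, loglik)
    d = len(state.theta)
    if sigma0 is None:
        # initial proposal covariance in transformed coordinates
        u0 = model.theta_to_u(state.theta)
        scale = np.maximum(0.1 * np.abs(u0), 0.01)
        sigma0 = np.diag(scale ** 2)
    j0 = cfg.jump if cfg.jump is not None else 2.38 / math.sqrt(d)
    adapt_state = AdaptState(sigma=np.atleast_2d(np.asarray(sigma0, float)),
                             j=j0, frozen=not adapt_enabled)

    total = cfg.burnin + cfg.updates
    thetas = np.empty((cfg.updates, d))
    logpost = np.empty(cfg.updates)
    is_pbp = np.zeros(cfg.updates, dtype=bool)
    accepted = np.zeros(cfg.updates, dtype=bool)
    latents = []
    counters = {"pbp": [0, 0], "std_latent": [0, 0], "std_param": [0, 0]}
    win = {"pbp": [0, 0], "lat": [0, 0], "par": [0, 0]}
    history = []

    for it in range(total):
        in_burn = it < cfg.burnin
        do_pbp = ids is not None and (it % cfg.interleave) < cfg.interleave - 1
        acc_flag = False
        if do_pbp:
            if plan is not None and hasattr(plan, "pbp_sweep"):
                state, acc_flag = _fast_pbp(state, model, plan, ids,
                                            adapt_state, cfg, rng)
            else:
                state, acc_flag, _ = pbp_update(state, model, ids,
                                                adapt_state, cfg, rng, loglik)
            win["pbp"][0] += acc_flag
            win["pbp"][1] += 1
            if not in_burn:
                counters["pbp"][0] += acc_flag
                counters["pbp"][1] += 1
        else:
            if plan is not None and hasattr(plan, "latent_sweep"):
                state, (la, lt) = _fast_standard_latents(state, plan,
                                                         adapt_state, rng)
                state, _, (pa, pt) = _params_only_update(state, model, rng,
                                                         adapt_state, loglik)
            else:
                state, (la, lt), (pa, pt) = standard_update(
                    state, model, rng, adapt_state, loglik)
            win["lat"][0] += la
            win["lat"][1] += lt
            win["par"][0] += pa
            win["par"][1] += pt
            if not in_burn:
                counters["std_latent"][0] += la
                counters["std_latent"][1] += lt
                counters["std_param"][0] += pa
                counters["std_param"][1] += pt
        if in_burn:
            history.append(model.theta_to_u(state.theta))
            if adapt_enabled and (it + 1) % cfg.adapt_window == 0:
                frac = (it + 1) / cfg.burnin
                _adapt_all(adapt_state, history, win, cfg, frac)
                for key in win:
                    win[key] = [0, 0]
        else:
            k = it - cfg.burnin
            thetas[k] = state.theta
            logpost[k] = state.log_posterior
            is_pbp[k] = do_pbp
            accepted[k] = acc_flag
            if cfg.store_latent and k % cfg.store_latent == 0:
                latents.append(state.xi.copy())

    counters = {k: tuple(v) for k, v in counters.items()}
    return Trace(list(model.param_names), thetas, logpost, is_pbp, accepted,
                 counters, latents, adapt_state.j, adapt_state.sigma.copy())


def _adapt_all(adapt_state, history, win, cfg, frac=0.0):
    """Two-stage adaptation.

    For the first 70% of burn-in both the proposal covariance and the jump
    scale are estimated by per-window multiplicative feedback (fast gain).
    In the final 30% the covariance is frozen and j is tuned by a
    measure-then-correct loop: j is held fixed over blocks of ten windows
    (feedback-free measurements of the acceptance rate are unbiased, unlike
    measurements taken while j itself is moving) and then corrected once
    per block through the empirical alpha ~ j^-1 power law.
    """
    pbp_rate = (win["pbp"][0] / win["pbp"][1]) if win["pbp"][1] else None
    if frac < 0.7:
        hist = np.asarray(history[len(history) // 4:])
        rate = cfg.target_accept if pbp_rate is None else pbp_rate
        adapt(adapt_state, hist, rate, cfg.target_accept, c=0.5)
    else:
        adapt_state.block_acc += win["pbp"][0]
        adapt_state.block_tot += win["pbp"][1]
        adapt_state.block_k += 1
        if adapt_state.block_k >= 10 and adapt_state.block_tot > 0:
            alpha = adapt_state.block_acc / adapt_state.block_tot
            ratio = alpha / cfg.target_accept if alpha > 0 else 0.3
            # full Newton step (alpha ~ 1/j) when far off, damped when close
            expo = 1.0 if ratio > 2.0 or ratio < 0.5 else 0.8
            adapt_state.j = float(np.clip(adapt_state.j * ratio ** expo,
                                          0.02, 10.0))
            adapt_state.block_acc = 0
            adapt_state.block_tot = 0
            adapt_state.block_k = 0
    if win["lat"][1]:
        rate = win["lat"][0] / win["lat"][1]
        adapt_state.lstep = float(np.clip(
            adapt_state.lstep * math.exp(0.3 * (rate - 0.44)), 1e-3, 1e3))
    if win["par"][1]:
        rate = win["par"][0] / win["par"][1]
        adapt_state.psteps = np.clip(
            adapt_state.psteps * math.exp(0.3 * (rate - 0.30)), 1e-6, 1e3)


def _params_only_update(state, model, rng, adapt_state, loglik):
    """Parameter part of the standard sweep (latents handled by a fast plan)."""
    par_acc = par_tot = 0
    gibbs_done = False
    for k, spec in enumerate(model.params):
        gibbs = model.param_gibbs.get(spec.name)
        if gibbs is not None:
            state.theta[k] = gibbs(state.xi, state.theta, rng)
            gibbs_done = True
            par_acc += 1
            par_tot += 1
            continue
        if gibbs_done:
            _refresh(state, model, loglik)
            gibbs_done = False
        theta_p = state.theta.copy()
        theta_p[k] += adapt_state.psteps[k] * rng.standard_normal()
        prior_p = model.prior_loglik(theta_p)
        par_tot += 1
        if prior_p == -np.inf:
            continue
        lat_p, obs_p = loglik(theta_p, state.xi)
        delta = (lat_p + obs_p + prior_p
                 - state.lat_ll - state.obs_ll - state.prior_ll)
        if delta >= 0 or math.log(rng.random()) < delta:
            state.theta = theta_p
            state.lat_ll, state.obs_ll, state.prior_ll = lat_p, obs_p, prior_p
            par_acc += 1
    if gibbs_done:
        _refresh(state, model, loglik)
    return state, None, (par_acc, par_tot)


def _fast_pbp(state, model, plan, ids, adapt_state, cfg, rng):
    u_p = propose_theta(model.theta_to_u(state.theta), adapt_state.chol,
                        adapt_state.j, rng)
    theta_p = model.theta_from_u(u_p)
    prior_p = model.prior_loglik(theta_p)
    if prior_p == -np.inf:
        return state, False
    log_jac = (model.proposal_log_jacobian(state.theta)
               - model.proposal_log_jacobian(theta_p))
    seed = int(rng.integers(1 << 31))
    out = plan.pbp_sweep(ids.level, state.xi, state.theta, theta_p, seed,
                         cfg.kappa)
    if out is None:
        return state, False
    xi_p, log_corr = out
    lat_p, obs_p = plan.logliks(theta_p, xi_p)
    log_alpha = ((lat_p + obs_p + prior_p)
                 - (state.lat_ll + state.obs_ll + state.prior_ll)
                 + log_corr + log_jac)
    if not np.isfinite(log_alpha):
        return state, False
    if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
        return ChainState(theta_p, xi_p, lat_p, obs_p, prior_p), True
    return state, False


def _fast_standard_latents(state, plan, adapt_state, rng):
    seed = int(rng.integers(1 << 31))
    xi_new, n_acc, n_tot = plan.latent_sweep(state.xi, state.theta, seed,
                                            adapt_state.lstep)
    state.xi = xi_new
    state.lat_ll, state.obs_ll = plan.logliks(state.theta, state.xi)
    return state, (int(n_acc), int(n_tot))
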