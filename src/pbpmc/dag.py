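"""DAG-structured latent-variable models.

A model is a set of named parameters theta with priors, an ordered list of
latent nodes (each node ``e`` has a distribution family and a map from the
preceding latent values and theta to that family's characteristic
parameters), and a set of observation terms.  Topological ordering — every
node's parents have strictly smaller indices — makes the latent likelihood a
product of univariate conditionals and lets the model be simulated forward
node by node.

The three log-likelihood components (latent, observation, prior) are exposed
separately because the posterior-based-proposal acceptance ratio needs them
separately.  Impossible states yield ``-inf`` rather than exceptions so the
Metropolis–Hastings step can reject them naturally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import kernels

__all__ = [
    "ParamSpec",
    "LatentNode",
    "ObsTerm",
    "DagModel",
    "ChainState",
    "sample_family",
]


def sample_family(family: str, values: dict, rng: np.random.Generator):
    """Draw one value (or an array, if parameters are arrays) from a family."""
    if family == "poisson":
        return rng.poisson(values["lam"])
    if family == "normal":
        return rng.normal(values["mu"], math.sqrt(values["var"]))
    if family == "lognormal":
        return float(np.exp(rng.normal(values["mu"], math.sqrt(values["var"]))))
    if family == "exponential":
        return rng.exponential(1.0 / values["rate"])
    if family == "gamma":
        return rng.gamma(values["alpha"], 1.0 / values["beta"])
    if family == "beta":
        return rng.beta(values["alpha"], values["beta"])
    if family == "bernoulli":
        return int(rng.random() < values["z"])
    if family == "binomial":
        return rng.binomial(int(values["n"]), values["z"])
    if family == "uniform":
        return rng.uniform(values["a"], values["b"])
    if family == "geometric":
        return rng.geometric(values["z"]) - 1
    if family == "negative_binomial":
        return rng.negative_binomial(values["r"], 1.0 - values["z"])
    raise ValueError(f"unsupported family {family!r}")


@dataclass
class ParamSpec:
    """One named model parameter with support bounds and prior.

    ``log_prior`` of ``None`` means a flat prior on ``(lo, hi)``; improper
    flat priors are allowed, in which case ``sample_init`` must be given so
    chains can be initialized.
    """

    name: str
    lo: float = -np.inf
    hi: float = np.inf
    log_prior: Optional[Callable[[float], float]] = None
    sample_init: Optional[Callable[[np.random.Generator], float]] = None
    #: coordinate used by the joint random-walk proposal: "identity",
    #: "log" (log(theta - lo)) or "logit" (over the finite support)
    transform: str = "identity"

    def __post_init__(self):
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log" and not np.isfinite(self.lo):
            raise ValueError("log transform needs a finite lower bound")
        if self.transform == "logit" and not (np.isfinite(self.lo)
                                              and np.isfinite(self.hi)):
            raise ValueError("logit transform needs finite bounds")

    def to_u(self, value: float) -> float:
        if self.transform == "log":
            return math.log(max(value - self.lo, 1e-300))
        if self.transform == "logit":
            z = (value - self.lo) / (self.hi - self.lo)
            z = min(max(z, 1e-15), 1 - 1e-15)
            return math.log(z / (1 - z))
        return value

    def from_u(self, u: float) -> float:
        if self.transform == "log":
            return self.lo + math.exp(min(u, 700.0))
        if self.transform == "logit":
            z = 1.0 / (1.0 + math.exp(-min(max(u, -700.0), 700.0)))
            return self.lo + z * (self.hi - self.lo)
        return u

    def log_jacobian(self, value: float) -> float:
        """log |du/dtheta| at theta = value (Hastings correction term)."""
        if self.transform == "log":
            return -math.log(max(value - self.lo, 1e-300))
        if self.transform == "logit":
            return (math.log(self.hi - self.lo)
                    - math.log(max(value - self.lo, 1e-300))
                    - math.log(max(self.hi - value, 1e-300)))
        return 0.0

    def prior_logpdf(self, value: float) -> float:
        if not (self.lo < value < self.hi):
            return -np.inf
        return 0.0 if self.log_prior is None else float(self.log_prior(value))

    def draw_init(self, rng: np.random.Generator) -> float:
        if self.sample_init is not None:
            return float(self.sample_init(rng))
        if np.isfinite(self.lo) and np.isfinite(self.hi):
            return float(rng.uniform(self.lo, self.hi))
        raise ValueError(
            f"parameter {self.name!r} has an unbounded support and no "
            "initialization sampler"
        )


@dataclass
class LatentNode:
    """Latent variable e with conditional family and parameter map.

    ``cond_params(xi, theta) -> dict`` may read only ``xi[p]`` for parent
    indices ``p < e``.
    """

    family: str
    cond_params: Callable[[np.ndarray, np.ndarray], dict]
    parents: tuple = ()


@dataclass
class ObsTerm:
    """One observation term with an explicit latent dependency set.

    ``logp(xi, theta, y)`` evaluates the observation log density;
    ``sample(xi, theta, rng)`` draws a synthetic observation.  ``value`` is
    the bound datum (None until data are attached).
    """

    deps: tuple
    logp: Callable
    sample: Optional[Callable] = None
    value: object = None


class DagModel:
    """Parameters + topologically ordered latent nodes + observation terms."""

    def __init__(self, params: Sequence[ParamSpec], nodes: Sequence[LatentNode],
                 obs: Sequence[ObsTerm] = (), name: str = "model"):
        self.params = list(params)
        self.nodes = list(nodes)
        self.obs = list(obs)
        self.name = name
        self.param_names = [p.name for p in self.params]
        self._pindex = {p.name: i for i, p in enumerate(self.params)}
        for e, node in enumerate(self.nodes):
            if any(p >= e for p in node.parents):
                raise ValueError(
                    f"node {e}: parent index >= {e} violates topological order"
                )
        self.children = [[] for _ in self.nodes]
        for e, node in enumerate(self.nodes):
            for p in node.parents:
                self.children[p].append(e)
        self.obs_by_node = [[] for _ in self.nodes]
        for r, term in enumerate(self.obs):
            for e in term.deps:
                self.obs_by_node[e].append(r)
        # optional hooks filled in by builders:
        self.fast_plans = {}          # id level / "baseline" -> fast sweep plan
        self.param_gibbs = {}         # param name -> gibbs sampler
        self.id1_rules = None         # node-wise ID1 CharParams function
        self.id2_rules = None
        self.extra_log_prior = None   # joint prior terms (e.g. identifiability)
        self.eval_count = 0           # instrumentation: density-term evaluations

    # -- indexing helpers ---------------------------------------------------
    def pidx(self, name: str) -> int:
        return self._pindex[name]

    # -- proposal-coordinate maps -------------------------------------------
    def theta_to_u(self, theta: np.ndarray) -> np.ndarray:
        return np.array([s.to_u(v) for s, v in zip(self.params, theta)])

    def theta_from_u(self, u: np.ndarray) -> np.ndarray:
        return np.array([s.from_u(v) for s, v in zip(self.params, u)])

    def proposal_log_jacobian(self, theta: np.ndarray) -> float:
        return sum(s.log_jacobian(v) for s, v in zip(self.params, theta))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    # -- likelihood components ---------------------------------------------
    def node_logp(self, e: int, xi: np.ndarray, theta: np.ndarray) -> float:
        self.eval_count += 1
        node = self.nodes[e]
        try:
            values = node.cond_params(xi, theta)
        except (ValueError, FloatingPointError):
            return -np.inf
        try:
            return float(kernels.log_density(node.family, values, xi[e]))
        except ValueError:
            return -np.inf

    def latent_loglik(self, theta: np.ndarray, xi: np.ndarray) -> float:
        """Sum of log conditionals over all nodes in topological order."""
        if len(xi) != self.n_nodes:
            raise ValueError("xi length does not match the number of nodes")
        total = 0.0
        for e in range(self.n_nodes):
            total += self.node_logp(e, xi, theta)
            if total == -np.inf:
                return -np.inf
        return total

    def obs_loglik(self, theta: np.ndarray, xi: np.ndarray) -> float:
        total = 0.0
        for term in self.obs:
            if term.value is None:
                raise ValueError("observation term has no bound data")
            self.eval_count += 1
            total += float(term.logp(xi, theta, term.value))
            if total == -np.inf:
                return -np.inf
        return total

    def prior_loglik(self, theta: np.ndarray) -> float:
        total = 0.0
        for spec, value in zip(self.params, theta):
            total += spec.prior_logpdf(value)
            if total == -np.inf:
                return -np.inf
        if self.extra_log_prior is not None:
            total += float(self.extra_log_prior(theta))
        return total

    # -- simulation ----------------------------------------------------------
    def simulate_forward(self, theta: np.ndarray, rng: np.random.Generator):
        """Joint forward draw of (latent values, observations) at theta."""
        xi = np.zeros(self.n_nodes)
        for e, node in enumerate(self.nodes):
            try:
                values = node.cond_params(xi, theta)
                xi[e] = sample_family(node.family, values, rng)
            except ValueError as err:
                raise ValueError(f"node {e}: invalid conditional parameters "
                                 f"({err})") from err
        ys = []
        for term in self.obs:
            if term.sample is None:
                raise ValueError("observation term has no sampler")
            ys.append(term.sample(xi, theta, rng))
        return xi, ys

    def bind_observations(self, ys: Sequence) -> None:
        if len(ys) != len(self.obs):
            raise ValueError("observation count mismatch")
        for term, y in zip(self.obs, ys):
            term.value = y

    @property
    def observations(self):
        return [term.value for term in self.obs]

    # -- local updates --------------------------------------------------------
    def delta_components(self, state: "ChainState", e: int, new_value):
        """(latent, observation) log-likelihood change if xi_e <- new_value.

        Touches only node e's own conditional, its children's conditionals,
        and observation terms whose dependency sets contain e.
        """
        xi, theta = state.xi, state.theta
        affected = [e] + self.children[e]
        old_lat = sum(self.node_logp(d, xi, theta) for d in affected)
        old_obs = sum(
            self._obs_term_logp(r, xi, theta) for r in self.obs_by_node[e]
        )
        old_value = xi[e]
        xi[e] = new_value
        new_lat = sum(self.node_logp(d, xi, theta) for d in affected)
        new_obs = sum(
            self._obs_term_logp(r, xi, theta) for r in self.obs_by_node[e]
        )
        xi[e] = old_value
        return new_lat - old_lat, new_obs - old_obs

    def delta_loglik(self, state: "ChainState", e: int, new_value) -> float:
        d_lat, d_obs = self.delta_components(state, e, new_value)
        return d_lat + d_obs

    def _obs_term_logp(self, r: int, xi, theta) -> float:
        self.eval_count += 1
        term = self.obs[r]
        return float(term.logp(xi, theta, term.value))


@dataclass
class ChainState:
    """Current (theta, xi) with cached log-likelihood components."""

    theta: np.ndarray
    xi: np.ndarray
    lat_ll: float
    obs_ll: float
    prior_ll: float

    @classmethod
    def from_values(cls, model: DagModel, theta, xi) -> "ChainState":
        theta = np.asarray(theta, dtype=float).copy()
        xi = np.asarray(xi, dtype=float).copy()
        return cls(theta, xi, model.latent_loglik(theta, xi),
                   model.obs_loglik(theta, xi), model.prior_loglik(theta))

    @property
    def log_posterior(self) -> float:
        return self.lat_ll + self.obs_ll + self.prior_ll

    def audit(self, model: DagModel, atol: float = 1e-9) -> None:
        """Assert that cached components match fresh recomputation."""
        fresh = (model.latent_loglik(self.theta, self.xi),
                 model.obs_loglik(self.theta, self.xi),
                 model.prior_loglik(self.theta))
        for cached, new in zip((self.lat_ll, self.obs_ll, self.prior_ll), fresh):
            if not (cached == new or abs(cached - new) < atol):
                raise AssertionError(
                    f"cache drift: cached={cached!r} fresh={new!r}"
                )

    def copy(self) -> "ChainState":
        return ChainState(self.theta.copy(), self.xi.copy(),
                          self.lat_ll, self.obs_ll, self.prior_ll)
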