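"""Latent-variable transition kernels for posterior-based proposals.

A kernel stochastically maps a latent value ``xi_i``, drawn under an initial
importance distribution F(params_i), to a proposed value ``xi_p`` such that

* **condition 1** (marginal preservation): if ``xi_i ~ F(params_i)`` then
  ``xi_p ~ F(params_p)`` exactly, and
* **condition 2** (identity limit): ``params_p == params_i`` implies
  ``xi_p == xi_i`` with probability one.

Eleven distribution families are supported (Poisson, normal, exponential,
gamma, beta, Bernoulli, binomial, uniform, geometric, negative binomial and
lognormal).  Condition 1 means the proposal density never has to be evaluated
in the Metropolis–Hastings ratio: only the importance-distribution densities
at the initial and proposed states enter, which :func:`id_log_density`
provides.  :func:`check_condition1` is a diagnostic that verifies marginal
preservation by exact enumeration (discrete families) or Monte Carlo
Kolmogorov–Smirnov distance (continuous families).

Parameter conventions
---------------------
poisson ``lam``; normal/lognormal ``mu``, ``var``; exponential ``rate``;
gamma ``alpha`` (shape), ``beta`` (rate); beta ``alpha``, ``beta``;
bernoulli ``z``; binomial ``n``, ``z``; uniform ``a``, ``b``; geometric
``z`` with pmf (1-z)^k z on k = 0, 1, ... (number of failures); negative
binomial ``r``, ``z`` with pmf C(k+r-1, k) z^k (1-z)^r.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAMILIES",
    "CharParams",
    "KernelConfig",
    "propose",
    "propose_poisson",
    "propose_normal",
    "propose_bernoulli",
    "propose_binomial",
    "propose_generic",
    "id_log_density",
    "log_density",
    "check_condition1",
]

#: families with a sampling scheme, a log density and a declared support
FAMILIES = (
    "poisson",
    "normal",
    "exponential",
    "gamma",
    "beta",
    "bernoulli",
    "binomial",
    "uniform",
    "geometric",
    "negative_binomial",
    "lognormal",
)

_DISCRETE = {"poisson", "bernoulli", "binomial", "geometric", "negative_binomial"}

_PARAM_NAMES = {
    "poisson": ("lam",),
    "normal": ("mu", "var"),
    "lognormal": ("mu", "var"),
    "exponential": ("rate",),
    "gamma": ("alpha", "beta"),
    "beta": ("alpha", "beta"),
    "bernoulli": ("z",),
    "binomial": ("n", "z"),
    "uniform": ("a", "b"),
    "geometric": ("z",),
    "negative_binomial": ("r", "z"),
}


@dataclass(frozen=True)
class CharParams:
    """Characteristic parameters of one importance-distribution family."""

    family: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        missing = set(_PARAM_NAMES[self.family]) - set(self.values)
        if missing:
            raise ValueError(f"{self.family}: missing parameters {sorted(missing)}")
        _validate(self.family, **self.values)

    def __getitem__(self, key):
        return self.values[key]


@dataclass(frozen=True)
class KernelConfig:
    """Tunables shared by all kernels.

    ``kappa`` controls the trade-off between deterministic rescaling
    (kappa=0) and independent resampling (kappa=1) in the normal and
    lognormal kernels.
    """

    kappa: float = 0.03

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")


def _validate(family, **v):
    def _chk(ok, msg):
        if not np.all(ok):
            raise ValueError(f"{family}: {msg}")

    if family == "poisson":
        _chk(np.asarray(v["lam"]) >= 0, "lam must be >= 0")
    elif family in ("normal", "lognormal"):
        _chk(np.asarray(v["var"]) > 0, "var must be > 0")
    elif family == "exponential":
        _chk(np.asarray(v["rate"]) > 0, "rate must be > 0")
    elif family in ("gamma", "beta"):
        _chk(np.asarray(v["alpha"]) > 0, "alpha must be > 0")
        _chk(np.asarray(v["beta"]) > 0, "beta must be > 0")
    elif family == "bernoulli":
        z = np.asarray(v["z"])
        _chk((z >= 0) & (z <= 1), "z must lie in [0, 1]")
    elif family == "binomial":
        n = np.asarray(v["n"])
        z = np.asarray(v["z"])
        _chk((n >= 0) & (n == np.floor(n)), "n must be a non-negative integer")
        _chk((z >= 0) & (z <= 1), "z must lie in [0, 1]")
    elif family == "uniform":
        _chk(np.asarray(v["a"]) < np.asarray(v["b"]), "need a < b")
    elif family == "geometric":
        z = np.asarray(v["z"])
        _chk((z > 0) & (z <= 1), "z must lie in (0, 1]")
    elif family == "negative_binomial":
        z = np.asarray(v["z"])
        _chk(np.asarray(v["r"]) > 0, "r must be > 0")
        _chk((z >= 0) & (z < 1), "z must lie in [0, 1)")


def _clip01(p):
    # absorb floating-point rounding in flip probabilities
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# samplers (raw-parameter core; broadcasting over xi_i and, where noted,
# over the parameters themselves)
# ---------------------------------------------------------------------------


def _poisson(lam_i, lam_p, xi, rng):
    lam_i, lam_p, xi = np.broadcast_arrays(lam_i, lam_p, np.asarray(xi))
    if np.any(np.asarray(xi) != np.floor(xi)) or np.any(np.asarray(xi) < 0):
        raise ValueError("poisson kernel: xi_i must be a non-negative integer")
    up = lam_p > lam_i
    add = rng.poisson(np.where(up, lam_p - lam_i, 0.0))
    denom = np.where(lam_i > 0, lam_i, 1.0)
    keep = _clip01(np.where(lam_i > 0, lam_p / denom, 1.0))
    thin = rng.binomial(xi.astype(np.int64), keep)
    return np.where(up, xi + add, thin)[()]


def _normal(mu_i, var_i, mu_p, var_p, xi, kappa, rng):
    mu_i, var_i, mu_p, var_p, xi = np.broadcast_arrays(
        mu_i, var_i, mu_p, var_p, np.asarray(xi, dtype=float)
    )
    up = var_p > var_i
    ratio = np.where(up, var_p / var_i, var_i / var_p)
    alpha = np.sqrt(kappa + (1.0 - kappa) * ratio)
    coef = np.where(up, alpha, alpha * var_p / var_i)
    var = np.where(
        up, kappa * (var_p - var_i), kappa * (var_p / var_i) * (var_i - var_p)
    )
    mean = mu_p + coef * (xi - mu_i)
    return (mean + np.sqrt(np.maximum(var, 0.0)) * rng.standard_normal(mean.shape))[()]


def _exponential(r_i, r_p, xi, rng):
    r_i, r_p, xi = np.broadcast_arrays(r_i, r_p, np.asarray(xi, dtype=float))
    up = r_p > r_i
    # rate increase: min with an independent Exp(r_p - r_i) arrival
    scale = np.where(up, 1.0 / np.where(up, r_p - r_i, 1.0), 1.0)
    x_up = np.minimum(xi, rng.exponential(scale))
    # rate decrease: with prob 1 - r_p/r_i extend by an Exp(r_p) excess
    extend = rng.random(xi.shape) < 1.0 - _clip01(r_p / r_i)
    x_dn = np.where(extend, xi + rng.exponential(1.0 / r_p), xi)
    return np.where(up, x_up, x_dn)[()]


def _gamma(a_i, b_i, a_p, b_p, xi, rng):
    a_i, b_i, a_p, b_p, xi = np.broadcast_arrays(
        a_i, b_i, a_p, b_p, np.asarray(xi, dtype=float)
    )
    up = a_p > a_i
    add = rng.gamma(np.where(up, a_p - a_i, 1.0), 1.0 / b_i)
    # Beta(a_p, 0) degenerates to the constant 1 (pure rescale)
    down = a_p < a_i
    y = np.where(down, rng.beta(a_p, np.where(down, a_i - a_p, 1.0)), 1.0)
    out = np.where(up, (b_i / b_p) * (xi + add), (b_i / b_p) * xi * y)
    return out[()]


def _bernoulli(z_i, z_p, xi, rng):
    z_i, z_p, xi = np.broadcast_arrays(z_i, z_p, np.asarray(xi))
    up = z_p > z_i
    u = rng.random(xi.shape)
    p_flip_up = _clip01(np.where(z_i < 1, (z_p - z_i) / np.where(z_i < 1, 1 - z_i, 1.0), 0.0))
    keep1 = _clip01(np.where(z_i > 0, z_p / np.where(z_i > 0, z_i, 1.0), 1.0))
    out_up = np.where(xi == 1, 1, (u < p_flip_up).astype(np.int64))
    out_dn = np.where(xi == 0, 0, (u < keep1).astype(np.int64))
    return np.where(up, out_up, out_dn)[()]


def _binomial(n_i, z_i, n_p, z_p, xi, rng):
    n_i, n_p = int(n_i), int(n_p)
    if z_i != z_p and n_i != n_p:
        # decompose a joint move: z first (at n_i), then n (at z_p)
        mid = _binomial(n_i, z_i, n_i, z_p, xi, rng)
        return _binomial(n_i, z_p, n_p, z_p, mid, rng)
    xi = np.asarray(xi)
    if np.any(xi < 0) or np.any(xi > n_i):
        raise ValueError("binomial kernel: xi_i outside {0..n_i}")
    if n_i == n_p:
        if z_p > z_i:
            return (xi + rng.binomial(n_i - xi, _clip01((z_p - z_i) / (1 - z_i))))[()]
        if z_p < z_i:
            return rng.binomial(xi, _clip01(z_p / z_i))[()]
        return xi[()]
    if n_p > n_i:
        return (xi + rng.binomial(n_p - n_i, z_i))[()]
    return rng.hypergeometric(n_p, n_i - n_p, xi)[()]


def _uniform(a_i, b_i, a_p, b_p, xi, rng=None):
    xi = np.asarray(xi, dtype=float)
    return (a_p + (xi - a_i) / (b_i - a_i) * (b_p - a_p))[()]


def _geom_failures(p, size, rng):
    # numpy's geometric counts trials (support 1, 2, ...)
    return rng.geometric(p, size=size) - 1


def _geometric(z_i, z_p, xi, rng):
    z_i, z_p, xi = np.broadcast_arrays(z_i, z_p, np.asarray(xi))
    up = z_p > z_i
    p_up = _clip01(np.where(up, (z_p - z_i) / (1 - z_i), 0.5))
    x_new = _geom_failures(np.where(p_up > 0, p_up, 0.5), xi.shape, rng)
    out_up = np.minimum(xi, x_new)
    keep = rng.random(xi.shape) >= 1.0 - _clip01(z_p / z_i)
    ext = _geom_failures(np.where(z_p > 0, z_p, 0.5), xi.shape, rng)
    out_dn = np.where(keep, xi, xi + 1 + ext)
    return np.where(up, out_up, out_dn)[()]


def _uniform_composition(total, parts, rng):
    """Uniform draw from the compositions of `total` into `parts` bins.

    All compositions of an iid geometric sum conditional on its total are
    equally likely, which is what makes this exact for the negative-binomial
    down-move.
    """
    if parts == 1:
        return np.array([total])
    if total == 0:
        return np.zeros(parts, dtype=np.int64)
    cuts = np.sort(rng.choice(total + parts - 1, size=parts - 1, replace=False))
    bounds = np.concatenate(([-1], cuts, [total + parts - 1]))
    return np.diff(bounds) - 1


def _negative_binomial(r_i, z_i, r_p, z_p, xi, rng):
    if z_i != z_p and r_i != r_p:
        mid = _negative_binomial(r_i, z_i, r_i, z_p, xi, rng)
        return _negative_binomial(r_i, z_p, r_p, z_p, mid, rng)
    xi = int(xi)
    if r_i == r_p:
        r = r_i
        if z_p > z_i:
            q = rng.binomial(int(round(r)), _clip01((z_p - z_i) / (1 - z_i)))
            x = rng.negative_binomial(q, 1 - z_p) if q > 0 else 0
            return xi + q + x
        if z_p < z_i:
            # split xi into r geometric components, thin each one
            r_int = int(round(r))
            if r_int != r:
                raise ValueError("negative binomial z-move needs integer r")
            parts = _uniform_composition(xi, r_int, rng)
            p_thin = 1.0 - _clip01(z_p / z_i)
            out = 0
            for g in parts:
                out += min(int(g), _geom_failures(p_thin, None, rng))
            return out
        return xi
    if r_p > r_i:
        return xi + rng.negative_binomial(r_p - r_i, 1 - z_i)
    # r decrease: negative hypergeometric NHG(xi + r_i - 1, xi, r_p)
    pmf = _nhg_pmf(xi + int(round(r_i)) - 1, xi, int(round(r_p)))
    return int(rng.choice(len(pmf), p=pmf))


def _nhg_pmf(n_tot, k_tot, r):
    """pmf of the negative hypergeometric NHG(N, K, r) on x = 0..K."""
    lg = math.lgamma
    def lcomb(n, k):
        if k < 0 or k > n:
            return -np.inf
        return lg(n + 1) - lg(k + 1) - lg(n - k + 1)
    xs = np.arange(k_tot + 1)
    logp = np.array(
        [lcomb(x + r - 1, x) + lcomb(n_tot - r - x, k_tot - x) - lcomb(n_tot, k_tot)
         for x in xs]
    )
    p = np.exp(logp - np.max(logp))
    return p / p.sum()


def _lognormal(mu_i, var_i, mu_p, var_p, xi, kappa, rng):
    return np.exp(_normal(mu_i, var_i, mu_p, var_p, np.log(xi), kappa, rng))


# ---------------------------------------------------------------------------
# public CharParams-level API
# ---------------------------------------------------------------------------


def propose(family, params_i, params_p, xi_i, rng, cfg=KernelConfig()):
    """Sample a proposed latent value via `family`'s case-branched scheme.

    ``params_i``/``params_p`` are dicts of raw parameter values (see module
    docstring for conventions).  Ties are routed to the branch that returns
    the identity, so equal parameters always reproduce ``xi_i``.
    """
    _validate(family, **params_i)
    _validate(family, **params_p)
    if family == "poisson":
        return _poisson(params_i["lam"], params_p["lam"], xi_i, rng)
    if family == "normal":
        return _normal(params_i["mu"], params_i["var"], params_p["mu"],
                       params_p["var"], xi_i, cfg.kappa, rng)
    if family == "lognormal":
        return _lognormal(params_i["mu"], params_i["var"], params_p["mu"],
                          params_p["var"], xi_i, cfg.kappa, rng)
    if family == "exponential":
        return _exponential(params_i["rate"], params_p["rate"], xi_i, rng)
    if family == "gamma":
        return _gamma(params_i["alpha"], params_i["beta"], params_p["alpha"],
                      params_p["beta"], xi_i, rng)
    if family == "beta":
        return _beta_kernel(params_i["alpha"], params_i["beta"], params_p["alpha"],
                            params_p["beta"], xi_i, rng)
    if family == "bernoulli":
        return _bernoulli(params_i["z"], params_p["z"], xi_i, rng)
    if family == "binomial":
        return _binomial(params_i["n"], params_i["z"], params_p["n"],
                         params_p["z"], xi_i, rng)
    if family == "uniform":
        return _uniform(params_i["a"], params_i["b"], params_p["a"],
                        params_p["b"], xi_i)
    if family == "geometric":
        return _geometric(params_i["z"], params_p["z"], xi_i, rng)
    if family == "negative_binomial":
        return _negative_binomial(params_i["r"], params_i["z"], params_p["r"],
                                  params_p["z"], xi_i, rng)
    raise ValueError(f"unsupported family {family!r}")


def _beta_kernel(a_i, b_i, a_p, b_p, xi, rng):
    if a_i != a_p and b_i != b_p:
        mid = _beta_kernel(a_i, b_i, a_p, b_i, xi, rng)
        return _beta_kernel(a_p, b_i, a_p, b_p, mid, rng)
    xi = np.asarray(xi, dtype=float)
    if a_p > a_i:
        x = rng.beta(b_i + a_i, a_p - a_i, size=xi.shape)
        return (1.0 - (1.0 - xi) * x)[()]
    if a_p < a_i:
        x = rng.beta(a_p, a_i - a_p, size=xi.shape)
        return (xi * x / (1.0 - xi * (1.0 - x)))[()]
    if b_p > b_i:
        x = rng.beta(a_i + b_i, b_p - b_i, size=xi.shape)
        return (xi * x)[()]
    if b_p < b_i:
        x = rng.beta(b_p, b_i - b_p, size=xi.shape)
        return (xi / (xi + (1.0 - xi) * x))[()]
    return xi[()]


def propose_generic(family, params_i, params_p, xi_i, cfg, rng):
    """Alias of :func:`propose` accepting :class:`CharParams` objects."""
    pi = params_i.values if isinstance(params_i, CharParams) else params_i
    pp = params_p.values if isinstance(params_p, CharParams) else params_p
    return propose(family, pi, pp, xi_i, rng, cfg)


def propose_poisson(params_i, params_p, xi_i, rng):
    return propose_generic("poisson", params_i, params_p, xi_i, KernelConfig(), rng)


def propose_normal(params_i, params_p, xi_i, cfg, rng):
    return propose_generic("normal", params_i, params_p, xi_i, cfg, rng)


def propose_bernoulli(params_i, params_p, xi_i, rng):
    return propose_generic("bernoulli", params_i, params_p, xi_i, KernelConfig(), rng)


def propose_binomial(params_i, params_p, xi_i, rng):
    return propose_generic("binomial", params_i, params_p, xi_i, KernelConfig(), rng)


# ---------------------------------------------------------------------------
# log densities (plain-math scalar/vector implementations; cross-checked
# against scipy.stats in the test suite)
# ---------------------------------------------------------------------------

_LGAMMA = np.vectorize(math.lgamma, otypes=[float])


def _with_support(logp, ok):
    return np.where(ok, logp, -np.inf)[()]


def log_density(family, params, xi):
    """Log pmf/pdf of `family` at `xi`; -inf outside the support."""
    v = params.values if isinstance(params, CharParams) else params
    _validate(family, **v)
    x = np.asarray(xi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "poisson":
            lam = np.asarray(v["lam"], dtype=float)
            ok = (x >= 0) & (x == np.floor(x))
            xs = np.where(ok, x, 0.0)
            logp = np.where(
                lam > 0,
                xs * np.log(np.where(lam > 0, lam, 1.0)) - lam - _LGAMMA(xs + 1),
                np.where(xs == 0, 0.0, -np.inf),
            )
            return _with_support(logp, ok)
        if family == "normal":
            mu, var = v["mu"], v["var"]
            return (-0.5 * np.log(2 * np.pi * var) - 0.5 * (x - mu) ** 2 / var)[()]
        if family == "lognormal":
            mu, var = v["mu"], v["var"]
            ok = x > 0
            xs = np.where(ok, x, 1.0)
            logp = (-np.log(xs) - 0.5 * np.log(2 * np.pi * var)
                    - 0.5 * (np.log(xs) - mu) ** 2 / var)
            return _with_support(logp, ok)
        if family == "exponential":
            r = v["rate"]
            return _with_support(np.log(r) - r * x, x >= 0)
        if family == "gamma":
            a, b = v["alpha"], v["beta"]
            ok = x > 0
            xs = np.where(ok, x, 1.0)
            logp = a * np.log(b) + (a - 1) * np.log(xs) - b * xs - _LGAMMA(a)
            return _with_support(logp, ok)
        if family == "beta":
            a, b = v["alpha"], v["beta"]
            ok = (x > 0) & (x < 1)
            xs = np.where(ok, x, 0.5)
            lb = _LGAMMA(a) + _LGAMMA(b) - _LGAMMA(a + b)
            logp = (a - 1) * np.log(xs) + (b - 1) * np.log1p(-xs) - lb
            return _with_support(logp, ok)
        if family == "bernoulli":
            z = np.asarray(v["z"], dtype=float)
            ok = (x == 0) | (x == 1)
            logp = np.where(x == 1, np.log(z), np.log1p(-z))
            return _with_support(logp, ok)
        if family == "binomial":
            n, z = np.asarray(v["n"]), np.asarray(v["z"], dtype=float)
            ok = (x >= 0) & (x <= n) & (x == np.floor(x))
            xs = np.where(ok, x, 0.0)
            lc = _LGAMMA(n + 1) - _LGAMMA(xs + 1) - _LGAMMA(n - xs + 1)
            t1 = np.where((z > 0) | (xs == 0), xs * np.log(np.where(z > 0, z, 1.0)), -np.inf)
            t0 = np.where((z < 1) | (xs == n), (n - xs) * np.log1p(np.where(z < 1, -z, 0.0)), -np.inf)
            return _with_support(lc + t1 + t0, ok)
        if family == "uniform":
            a, b = v["a"], v["b"]
            return _with_support(-np.log(b - a) * np.ones_like(x), (x >= a) & (x <= b))
        if family == "geometric":
            z = v["z"]
            ok = (x >= 0) & (x == np.floor(x))
            return _with_support(x * np.log1p(-z) + np.log(z), ok)
        if family == "negative_binomial":
            r, z = v["r"], v["z"]
            ok = (x >= 0) & (x == np.floor(x))
            xs = np.where(ok, x, 0.0)
            lc = _LGAMMA(xs + r) - _LGAMMA(xs + 1) - _LGAMMA(r)
            logp = lc + xs * np.log(np.where(z > 0, z, 1.0)) + r * np.log1p(-z)
            logp = np.where((z > 0) | (xs == 0), logp, -np.inf)
            return _with_support(logp, ok)
    raise ValueError(f"unsupported family {family!r}")


def id_log_density(family, params, xi):
    """Alias of :func:`log_density` (the name used in the sampler core)."""
    return log_density(family, params, xi)


# ---------------------------------------------------------------------------
# condition-1 diagnostic
# ---------------------------------------------------------------------------


def _trunc_grid(family, v, tail=1e-12):
    """Integer grid covering all but `tail` of the pmf mass."""
    from scipy import stats

    if family == "poisson":
        hi = int(stats.poisson.ppf(1 - tail, max(v["lam"], 1e-12))) + 1
    elif family == "bernoulli":
        hi = 1
    elif family == "binomial":
        hi = int(v["n"])
    elif family == "geometric":
        hi = int(stats.geom.ppf(1 - tail, v["z"]))
    elif family == "negative_binomial":
        hi = int(stats.nbinom.ppf(1 - tail, v["r"], 1 - v["z"])) + 1
    else:
        raise ValueError(family)
    return np.arange(hi + 1)


def _transition_row(family, vi, vp, x, grid):
    """Exact law of xi_p given xi_i = x, as a vector over `grid`."""
    from scipy import stats

    row = np.zeros(len(grid))
    if family == "poisson":
        li, lp = vi["lam"], vp["lam"]
        if lp > li:
            row = stats.poisson.pmf(grid - x, lp - li)
        else:
            ratio = lp / li if li > 0 else 1.0
            row = stats.binom.pmf(grid, x, ratio)
    elif family == "bernoulli":
        zi, zp = vi["z"], vp["z"]
        if zp > zi:
            pf = (zp - zi) / (1 - zi) if zi < 1 else 0.0
            row[1] += 1.0 if x == 1 else pf
            if x == 0:
                row[0] += 1 - pf
        else:
            keep = zp / zi if zi > 0 else 1.0
            if x == 0:
                row[0] = 1.0
            else:
                row[1], row[0] = keep, 1 - keep
    elif family == "binomial":
        ni, zi = int(vi["n"]), vi["z"]
        npar, zp = int(vp["n"]), vp["z"]
        if ni == npar:
            if zp > zi:
                row = stats.binom.pmf(grid - x, ni - x, (zp - zi) / (1 - zi))
            elif zp < zi:
                row = stats.binom.pmf(grid, x, zp / zi)
            else:
                row[x] = 1.0
        elif npar > ni:
            row = stats.binom.pmf(grid - x, npar - ni, zi)
        else:
            row = stats.hypergeom.pmf(grid, ni, npar, x)
    elif family == "geometric":
        zi, zp = vi["z"], vp["z"]
        if zp > zi:
            pf = (zp - zi) / (1 - zi)
            for k, g in enumerate(grid):
                if g < x:
                    row[k] = stats.geom.pmf(g + 1, pf)
                elif g == x:
                    row[k] = stats.geom.sf(x, pf) + stats.geom.pmf(x + 1, pf) * 0
                    row[k] = (1 - pf) ** x  # P(X >= x)
        else:
            keep = zp / zi
            row[grid == x] = keep
            mask = grid > x
            row[mask] = (1 - keep) * stats.geom.pmf(grid[mask] - x, zp)
    elif family == "negative_binomial":
        ri, zi = vi["r"], vi["z"]
        rp, zp = vp["r"], vp["z"]
        if ri == rp:
            r = int(round(ri))
            if zp > zi:
                pf = (zp - zi) / (1 - zi)
                for q in range(r + 1):
                    wq = stats.binom.pmf(q, r, pf)
                    if q == 0:
                        row[grid == x] += wq
                    else:
                        m = grid >= x + q
                        row[m] += wq * stats.nbinom.pmf(grid[m] - x - q, q, 1 - zp)
            elif zp < zi:
                row = _nb_down_row(r, 1.0 - zp / zi, x, grid)
            else:
                row[grid == x] = 1.0
        elif rp > ri:
            row = stats.nbinom.pmf(grid - x, rp - ri, 1 - zi)
        else:
            pmf = _nhg_pmf(x + int(round(ri)) - 1, x, int(round(rp)))
            row[: len(pmf)] = pmf
    else:
        raise ValueError(family)
    return row


def _nb_down_row(r, p_thin, x, grid):
    """Transition law of the component-wise negative-binomial down-move."""
    from scipy import stats

    def thinned(g):
        # law of min(g, Geom(p_thin)) on 0..g
        p = np.zeros(g + 1)
        ks = np.arange(g)
        p[:g] = stats.geom.pmf(ks + 1, p_thin)
        p[g] = (1 - p_thin) ** g
        return p

    total = np.zeros(x + 1)
    comps = [c for c in itertools.product(range(x + 1), repeat=r) if sum(c) == x]
    for comp in comps:
        dist = np.array([1.0])
        for g in comp:
            dist = np.convolve(dist, thinned(g))
        total += dist / len(comps)
    row = np.zeros(len(grid))
    row[: x + 1] = total
    return row


def check_condition1(family, params_i, params_p, cfg=KernelConfig(),
                     n_mc=200_000, seed=0):
    """Maximum deviation of the pushed-forward marginal from its target.

    Discrete families are checked by exact enumeration of the transition law
    on a truncated grid (returned value is the max absolute pmf deviation);
    continuous families by a Monte Carlo Kolmogorov–Smirnov distance between
    kernel outputs (inputs drawn from F(params_i)) and F(params_p).
    """
    from scipy import stats

    vi = params_i.values if isinstance(params_i, CharParams) else params_i
    vp = params_p.values if isinstance(params_p, CharParams) else params_p
    if family == "lognormal":
        # exact log-scale reduction to the normal case
        return check_condition1("normal", vi, vp, cfg, n_mc, seed)
    if family in _DISCRETE:
        # joint two-parameter moves are decomposed exactly as the sampler does
        stages = [(vi, vp)]
        if family == "binomial" and vi["z"] != vp["z"] and vi["n"] != vp["n"]:
            mid = {"n": vi["n"], "z": vp["z"]}
            stages = [(vi, mid), (mid, vp)]
        if (family == "negative_binomial"
                and vi["z"] != vp["z"] and vi["r"] != vp["r"]):
            mid = {"r": vi["r"], "z": vp["z"]}
            stages = [(vi, mid), (mid, vp)]
        n_grid = max(len(_trunc_grid(family, v))
                     for pair in stages for v in pair)
        grid = np.arange(n_grid)
        pushed = np.exp([log_density(family, vi, g) for g in grid])
        for va, vb in stages:
            nxt = np.zeros(n_grid)
            for x, w in zip(grid, pushed):
                if w < 1e-300:
                    continue
                nxt += w * _transition_row(family, va, vb, int(x), grid)
            pushed = nxt
        target = np.exp([log_density(family, vp, g) for g in grid])
        return float(np.max(np.abs(pushed - target)))

    rng = np.random.default_rng(seed)
    if family == "normal":
        xi = rng.normal(vi["mu"], math.sqrt(vi["var"]), n_mc)
        out = _normal(vi["mu"], vi["var"], vp["mu"], vp["var"], xi, cfg.kappa, rng)
        cdf = stats.norm(vp["mu"], math.sqrt(vp["var"])).cdf
    elif family == "exponential":
        xi = rng.exponential(1.0 / vi["rate"], n_mc)
        out = _exponential(vi["rate"], vp["rate"], xi, rng)
        cdf = stats.expon(scale=1.0 / vp["rate"]).cdf
    elif family == "gamma":
        xi = rng.gamma(vi["alpha"], 1.0 / vi["beta"], n_mc)
        out = _gamma(vi["alpha"], vi["beta"], vp["alpha"], vp["beta"], xi, rng)
        cdf = stats.gamma(vp["alpha"], scale=1.0 / vp["beta"]).cdf
    elif family == "beta":
        xi = rng.beta(vi["alpha"], vi["beta"], n_mc)
        out = _beta_kernel(vi["alpha"], vi["beta"], vp["alpha"], vp["beta"], xi, rng)
        cdf = stats.beta(vp["alpha"], vp["beta"]).cdf
    elif family == "uniform":
        xi = rng.uniform(vi["a"], vi["b"], n_mc)
        out = _uniform(vi["a"], vi["b"], vp["a"], vp["b"], xi)
        cdf = stats.uniform(vp["a"], vp["b"] - vp["a"]).cdf
    else:
        raise ValueError(f"unsupported family {family!r}")
    out = np.sort(np.asarray(out))
    ecdf_hi = np.arange(1, n_mc + 1) / n_mc
    ecdf_lo = np.arange(0, n_mc) / n_mc
    c = cdf(out)
    return float(max(np.max(np.abs(ecdf_hi - c)), np.max(np.abs(ecdf_lo - c))))
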