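"""Kernel-level properties: marginal preservation, identity limit, support
closure, and density correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbpmc import kernels
from pbpmc.kernels import (
    CharParams,
    KernelConfig,
    check_condition1,
    log_density,
    propose,
)

# parameter pairs spanning both case branches of every family
GRID = [
    ("poisson", {"lam": 1.0}, {"lam": 2.5}),
    ("poisson", {"lam": 2.5}, {"lam": 1.0}),
    ("poisson", {"lam": 0.0}, {"lam": 3.0}),
    ("poisson", {"lam": 3.0}, {"lam": 0.0}),
    ("bernoulli", {"z": 0.3}, {"z": 0.6}),
    ("bernoulli", {"z": 0.6}, {"z": 0.3}),
    ("bernoulli", {"z": 0.0}, {"z": 1.0}),
    ("binomial", {"n": 10, "z": 0.2}, {"n": 10, "z": 0.7}),
    ("binomial", {"n": 10, "z": 0.7}, {"n": 10, "z": 0.2}),
    ("binomial", {"n": 6, "z": 0.4}, {"n": 12, "z": 0.4}),
    ("binomial", {"n": 12, "z": 0.4}, {"n": 6, "z": 0.4}),
    ("binomial", {"n": 8, "z": 0.3}, {"n": 5, "z": 0.6}),
    ("geometric", {"z": 0.3}, {"z": 0.6}),
    ("geometric", {"z": 0.6}, {"z": 0.3}),
    ("negative_binomial", {"r": 3, "z": 0.3}, {"r": 3, "z": 0.6}),
    ("negative_binomial", {"r": 3, "z": 0.6}, {"r": 3, "z": 0.3}),
    ("negative_binomial", {"r": 2, "z": 0.4}, {"r": 5, "z": 0.4}),
    ("negative_binomial", {"r": 5, "z": 0.4}, {"r": 2, "z": 0.4}),
    ("negative_binomial", {"r": 2, "z": 0.5}, {"r": 3, "z": 0.3}),
    ("normal", {"mu": 0.0, "var": 1.0}, {"mu": 2.0, "var": 9.0}),
    ("normal", {"mu": 2.0, "var": 9.0}, {"mu": 0.0, "var": 1.0}),
    ("lognormal", {"mu": 0.0, "var": 1.0}, {"mu": 0.5, "var": 2.0}),
    ("lognormal", {"mu": 0.5, "var": 2.0}, {"mu": 0.0, "var": 1.0}),
    ("exponential", {"rate": 1.0}, {"rate": 2.5}),
    ("exponential", {"rate": 2.5}, {"rate": 1.0}),
    ("gamma", {"alpha": 2.0, "beta": 1.0}, {"alpha": 4.0, "beta": 2.0}),
    ("gamma", {"alpha": 4.0, "beta": 2.0}, {"alpha": 2.0, "beta": 1.0}),
    ("beta", {"alpha": 2.0, "beta": 3.0}, {"alpha": 4.0, "beta": 3.0}),
    ("beta", {"alpha": 4.0, "beta": 3.0}, {"alpha": 2.0, "beta": 3.0}),
    ("beta", {"alpha": 2.0, "beta": 3.0}, {"alpha": 2.0, "beta": 5.0}),
    ("beta", {"alpha": 2.0, "beta": 5.0}, {"alpha": 2.0, "beta": 3.0}),
    ("beta", {"alpha": 2.0, "beta": 3.0}, {"alpha": 3.0, "beta": 5.0}),
    ("uniform", {"a": 0.0, "b": 1.0}, {"a": 2.0, "b": 4.0}),
]

DISCRETE = {"poisson", "bernoulli", "binomial", "geometric",
            "negative_binomial"}
N_MC = 100_000


@pytest.mark.parametrize("family,vi,vp", GRID,
                         ids=[f"{f}-{i}" for i, (f, _, _) in enumerate(GRID)])
def test_marginal_preservation(family, vi, vp):
    """Pushing the initial marginal through the kernel gives the proposed
    marginal: exactly for discrete families, to MC accuracy otherwise."""
    dev = check_condition1(family, vi, vp, n_mc=N_MC, seed=5)
    if family in DISCRETE:
        assert dev < 1e-10
    else:
        assert dev < 3.0 / math.sqrt(N_MC)


@pytest.mark.parametrize("family,vi,vp", GRID[::3])
def test_identity_limit(family, vi, vp, rng):
    """Equal initial and proposed parameters reproduce the input exactly."""
    draws = 10_000
    xi = _draw(family, vi, draws, rng)
    if family == "negative_binomial":
        out = np.array([propose(family, vi, vi, x, rng) for x in xi])
    else:
        out = propose(family, vi, vi, xi, rng)
    if family in DISCRETE or family == "uniform":
        np.testing.assert_array_equal(np.asarray(out, float),
                                      np.asarray(xi, float))
    else:
        np.testing.assert_allclose(out, xi, rtol=1e-12)


def _draw(family, v, n, rng):
    if family == "negative_binomial":
        return np.array([rng.negative_binomial(v["r"], 1 - v["z"])
                         for _ in range(min(n, 200))])
    mapping = {
        "poisson": lambda: rng.poisson(v["lam"], n),
        "bernoulli": lambda: (rng.random(n) < v["z"]).astype(int),
        "binomial": lambda: rng.binomial(v["n"], v["z"], n),
        "geometric": lambda: rng.geometric(max(v["z"], 1e-9), n) - 1,
        "normal": lambda: rng.normal(v["mu"], math.sqrt(v["var"]), n),
        "lognormal": lambda: np.exp(rng.normal(v["mu"], math.sqrt(v["var"]),
                                               n)),
        "exponential": lambda: rng.exponential(1 / v["rate"], n),
        "gamma": lambda: rng.gamma(v["alpha"], 1 / v["beta"], n),
        "beta": lambda: rng.beta(v["alpha"], v["beta"], n),
        "uniform": lambda: rng.uniform(v["a"], v["b"], n),
    }
    return mapping[family]()


@pytest.mark.parametrize("family,vi,vp", GRID)
def test_support_closure(family, vi, vp, rng):
    """Kernel outputs always lie in the proposed family's support."""
    xi = _draw(family, vi, 2000, rng)
    if family == "negative_binomial":
        out = np.array([propose(family, vi, vp, x, rng) for x in xi])
    else:
        out = np.asarray(propose(family, vi, vp, xi, rng))
    if family in DISCRETE:
        assert np.all(out == np.floor(out))
        assert np.all(out >= 0)
        if family == "binomial":
            assert np.all(out <= vp["n"])
        if family == "bernoulli":
            assert np.all((out == 0) | (out == 1))
    elif family == "beta":
        assert np.all((out >= 0) & (out <= 1))
    elif family in ("gamma", "exponential", "lognormal"):
        assert np.all(out >= 0)
    elif family == "uniform":
        assert np.all((out >= vp["a"]) & (out <= vp["b"]))


@given(var_i=st.floats(0.1, 50), var_p=st.floats(0.1, 50),
       kappa=st.floats(0.0, 1.0))
@settings(max_examples=200, deadline=None)
def test_normal_variance_identity(var_i, var_p, kappa):
    """alpha^2 var_i + kappa (var_p - var_i) = var_p, and its mirror."""
    if var_p > var_i:
        alpha2 = kappa + (1 - kappa) * var_p / var_i
        total = alpha2 * var_i + kappa * (var_p - var_i)
    else:
        alpha2 = kappa + (1 - kappa) * var_i / var_p
        coef2 = alpha2 * (var_p / var_i) ** 2
        total = coef2 * var_i + kappa * (var_p / var_i) * (var_i - var_p)
    assert total == pytest.approx(var_p, rel=1e-12)


@pytest.mark.parametrize("family,v", [(f, vi) for f, vi, _ in GRID[::2]])
def test_density_normalization(family, v):
    """Exponentiated log densities sum/integrate to one."""
    if family in DISCRETE:
        grid = np.arange(0, 400)
        total = np.exp([log_density(family, v, g) for g in grid]).sum()
        assert total == pytest.approx(1.0, abs=1e-9)
    else:
        from scipy.integrate import quad

        if family == "uniform":
            lo, hi = v["a"], v["b"]
        else:
            lo, hi = {
                "normal": (-60, 60), "lognormal": (1e-12, 1e4),
                "exponential": (0, 200), "gamma": (0, 200), "beta": (0, 1),
            }[family]
        total, _ = quad(lambda x: math.exp(log_density(family, v, x)),
                        lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize(
    "family,v,dist",
    [
        ("poisson", {"lam": 2.0}, stats.poisson(2.0)),
        ("normal", {"mu": 1.0, "var": 4.0}, stats.norm(1.0, 2.0)),
        ("lognormal", {"mu": 0.5, "var": 2.0},
         stats.lognorm(math.sqrt(2.0), scale=math.exp(0.5))),
        ("exponential", {"rate": 2.5}, stats.expon(scale=0.4)),
        ("gamma", {"alpha": 3.0, "beta": 2.0}, stats.gamma(3.0, scale=0.5)),
        ("beta", {"alpha": 2.0, "beta": 5.0}, stats.beta(2.0, 5.0)),
        ("bernoulli", {"z": 0.25}, stats.bernoulli(0.25)),
        ("binomial", {"n": 9, "z": 0.3}, stats.binom(9, 0.3)),
        ("uniform", {"a": -1.0, "b": 3.0}, stats.uniform(-1.0, 4.0)),
        ("geometric", {"z": 0.3}, stats.geom(0.3, loc=-1)),
        ("negative_binomial", {"r": 3.0, "z": 0.4}, stats.nbinom(3, 0.6)),
    ],
)
def test_log_density_matches_scipy(family, v, dist):
    """Independent cross-check of every density against scipy.stats."""
    xs = (np.arange(0, 12) if family in DISCRETE or family == "bernoulli"
          else np.linspace(0.05, 2.5, 9))
    if family == "bernoulli":
        xs = np.array([0, 1])
    if family == "uniform":
        xs = np.linspace(-0.9, 2.9, 9)
    if family == "normal":
        xs = np.linspace(-4, 6, 9)
    ours = np.array([log_density(family, v, x) for x in xs])
    logf = dist.logpmf if family in DISCRETE or family == "bernoulli" \
        else dist.logpdf
    np.testing.assert_allclose(ours, logf(xs), rtol=1e-10, atol=1e-10)


def test_poisson_example_semantics(rng):
    """An upward Poisson move adds the sampled increment (e.g. 5 + 8 = 13),
    a move to zero intensity empties the count."""
    class FixedPoisson:
        def poisson(self, lam):
            return np.broadcast_to(8, np.shape(lam))
        def binomial(self, n, p):
            return np.asarray(n)
    out = kernels._poisson(1.0, 4.0, 5, FixedPoisson())
    assert out == 13
    assert propose("poisson", {"lam": 3.0}, {"lam": 0.0}, 7, rng) == 0


def test_bernoulli_sure_flip(rng):
    assert propose("bernoulli", {"z": 0.2}, {"z": 1.0}, 0, rng) == 1
    assert propose("bernoulli", {"z": 0.9}, {"z": 0.0}, 1, rng) == 0


def test_bernoulli_marginal_example(rng):
    """z 0.3 -> 0.6: enumerating the four (input, flip) outcomes gives
    output probability exactly 0.6."""
    z_i, z_p = 0.3, 0.6
    flip = (z_p - z_i) / (1 - z_i)
    assert z_i * 1.0 + (1 - z_i) * flip == pytest.approx(z_p)
    dev = check_condition1("bernoulli", {"z": z_i}, {"z": z_p})
    assert dev < 1e-12


def test_kappa_zero_is_affine(rng):
    """kappa = 0 degenerates the normal kernel to a deterministic rescale."""
    cfg = KernelConfig(kappa=0.0)
    xi = np.array([-1.0, 0.3, 2.0])
    out = propose("normal", {"mu": 0.0, "var": 1.0},
                  {"mu": 2.0, "var": 9.0}, xi, rng, cfg)
    np.testing.assert_allclose(out, 2.0 + 3.0 * xi, rtol=1e-12)


def test_domain_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        propose("poisson", {"lam": -1.0}, {"lam": 2.0}, 1, rng)
    with pytest.raises(ValueError):
        propose("normal", {"mu": 0, "var": -1.0}, {"mu": 0, "var": 1.0},
                0.0, rng)
    with pytest.raises(ValueError):
        propose("bernoulli", {"z": 1.4}, {"z": 0.5}, 1, rng)
    with pytest.raises(ValueError):
        propose("poisson", {"lam": 1.0}, {"lam": 2.0}, 1.5, rng)
    with pytest.raises(ValueError):
        propose("wishart", {}, {}, 0, rng)
    with pytest.raises(ValueError):
        CharParams("binomial", {"n": 3.5, "z": 0.2})
    with pytest.raises(ValueError):
        KernelConfig(kappa=1.5)


def test_char_params_container():
    cp = CharParams("normal", {"mu": 1.0, "var": 2.0})
    assert cp["mu"] == 1.0
    with pytest.raises(ValueError):
        CharParams("normal", {"mu": 0.0})
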