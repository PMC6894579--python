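"""Benchmark simulators and fast plans: generating-process statistics,
pedigree algebra, and agreement between compiled and generic code paths."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from pbpmc.benchmarks import (
    DiagnosticScenario,
    LogisticScenario,
    MixedScenario,
    SvtScenario,
    build_mixed,
    build_svt,
    relationship_matrix,
    simulate_pedigree,
    simulate_scenario,
)
from pbpmc.engine import EngineConfig, run_chain
from pbpmc.importance import make_id0


def test_simulation_seed_determinism():
    for scn in (DiagnosticScenario(P=50), SvtScenario(E=50),
                MixedScenario(generations=2, per_gen=10),
                LogisticScenario(T=41, M=5)):
        a = simulate_scenario(scn, np.random.default_rng(3))
        b = simulate_scenario(scn, np.random.default_rng(3))
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])


def test_diagnostic_positive_fraction_closed_form(rng):
    scn = DiagnosticScenario(P=60_000, p_D=0.3, se=(0.7, 0.6),
                             sp=(0.95, 0.85))
    data = scn.simulate(rng)["data"]
    expected = 0.3 * 0.7 + 0.7 * 0.05
    frac = data["y1"].mean()
    se3 = 3 * math.sqrt(expected * (1 - expected) / scn.P)
    assert abs(frac - expected) < se3


def test_svt_stationary_variance(rng):
    scn = SvtScenario(E=20_000, phi=0.9, sigma2=0.04)
    h = scn.simulate(rng)["latent_truth"]["h"].to_numpy()
    target = scn.sigma2 / (1 - scn.phi ** 2)
    assert h.var() == pytest.approx(target, rel=0.15)
    assert h.mean() == pytest.approx(scn.mu, abs=0.2)


def test_svt_invalid_phi_rejected():
    with pytest.raises(ValueError):
        SvtScenario(phi=1.2)
    with pytest.raises(ValueError):
        SvtScenario(nu=1.5)


def test_pedigree_single_generation_identity(rng):
    ped = simulate_pedigree(1, 6, rng)
    assert (ped["sire"] == 0).all() and (ped["dam"] == 0).all()
    np.testing.assert_array_equal(relationship_matrix(ped), np.eye(6))


def test_pedigree_relationship_entries(rng):
    # two founders, two full sibs, one grand-offspring
    ped = pd.DataFrame({
        "id": [1, 2, 3, 4, 5],
        "sire": [0, 0, 1, 1, 3],
        "dam": [0, 0, 2, 2, 4],
    })
    a = relationship_matrix(ped)
    assert a[0, 2] == pytest.approx(0.5)      # parent-offspring
    assert a[2, 3] == pytest.approx(0.5)      # full sibs
    assert a[2, 4] == pytest.approx(0.75)     # parent that is also uncle/aunt
    assert a[4, 4] == pytest.approx(1.25)     # inbred: parents are full sibs


def test_mixed_breeding_values_match_sigma_a2_A(rng):
    """Monte Carlo covariance of simulated breeding values reproduces
    sigma_a^2 times the tabular-method relationship matrix."""
    ped = pd.DataFrame({
        "id": [1, 2, 3, 4, 5],
        "sire": [0, 0, 1, 1, 3],
        "dam": [0, 0, 2, 2, 4],
    })
    scn = MixedScenario(r2=0.8, var_total=1.0)
    n_rep = 6000
    sims = np.array([
        scn.simulate(rng, pedigree=ped)["latent_truth"]["a"].to_numpy()
        for _ in range(n_rep)
    ])
    emp = np.cov(sims.T)
    target = scn.sigma_a2 * relationship_matrix(ped)
    se = 3 * (np.abs(target) + 0.5) / math.sqrt(n_rep / 3)
    assert np.all(np.abs(emp - target) < se)


def test_mixed_zero_heritability_collapses(rng):
    scn = MixedScenario(generations=2, per_gen=5, r2=0.0)
    a = scn.simulate(rng)["latent_truth"]["a"].to_numpy()
    np.testing.assert_allclose(a, 0.0, atol=1e-12)


def test_mixed_rejects_disordered_pedigree(rng):
    ped = pd.DataFrame({"id": [1, 2], "sire": [2, 0], "dam": [0, 0]})
    data = pd.DataFrame({"individual": [1, 2], "x1": [0.0, 1.0],
                         "record": [0.1, 0.2]})
    with pytest.raises(ValueError, match="parents before"):
        build_mixed(MixedScenario(), data=data, pedigree=ped)


def test_logistic_zero_birth_rate_decays(rng):
    scn = LogisticScenario(T=101, r_b=0.0, P0=50, M=3)
    pops = np.array([
        scn.simulate(rng)["latent_truth"]["P"].to_numpy()
        for _ in range(200)
    ])
    mean = pops.mean(axis=0)
    assert np.all(np.diff(mean) < 1e-9)


def test_logistic_tracks_ode(rng):
    """Pre-equilibrium mean trajectory follows the deterministic logistic
    birth-death ODE within 5%."""
    # founding population large enough that stochastic extinction (which
    # the deterministic ODE cannot represent) is negligible
    scn = LogisticScenario(T=201, P0=20, M=3)
    pops = np.array([
        scn.simulate(rng)["latent_truth"]["P"].to_numpy()
        for _ in range(1000)
    ])
    assert (pops[:, -1] == 0).mean() == 0.0
    mean = pops.mean(axis=0)

    def rhs(t, p):
        return scn.r_b * p * (1 - p / scn.K) - scn.mu * p

    ts = scn.tau * np.arange(scn.T)
    sol = solve_ivp(rhs, (0, ts[-1]), [scn.P0], t_eval=ts, rtol=1e-8)
    ode = sol.y[0]
    window = (ode > 21) & (ode < 45)       # growth phase
    rel = np.abs(mean[window] - ode[window]) / ode[window]
    assert np.max(rel) < 0.05


def test_logistic_equilibrium_level(rng):
    scn = LogisticScenario(T=401, M=3)
    pops = np.array([
        scn.simulate(rng)["latent_truth"]["P"].to_numpy()[-100:]
        for _ in range(300)
    ])
    eq = scn.K * (1 - scn.mu / scn.r_b)
    assert pops.mean() == pytest.approx(eq, rel=0.05)


# --- compiled fast paths vs the generic implementation ----------------------


@pytest.mark.parametrize("bench", ["diag_small", "svt_small", "mixed_small",
                                   "logistic_small"])
def test_fast_logliks_match_generic(bench, request):
    _, model, _ = request.getfixturevalue(bench)
    plan = model.fast_plans["baseline"]
    r = np.random.default_rng(21)
    for _ in range(5):
        theta = np.array([s.draw_init(r) for s in model.params])
        try:
            xi, _ = model.simulate_forward(theta, r)
        except ValueError:
            continue
        lat_g = model.latent_loglik(theta, xi)
        obs_g = model.obs_loglik(theta, xi)
        lat_f, obs_f = plan.logliks(theta, xi)
        # the logistic plan reports a single merged total
        assert lat_f + obs_f == pytest.approx(lat_g + obs_g, abs=1e-7)


@pytest.mark.parametrize("bench", ["svt_small", "mixed_small",
                                   "logistic_small"])
def test_fast_pbp_id0_correction_identity(bench, request):
    """For compiled ID0 sweeps the correction term must equal minus the
    latent-likelihood change — the same cancellation the generic path has."""
    _, model, _ = request.getfixturevalue(bench)
    plan = model.fast_plans[0]
    r = np.random.default_rng(22)
    theta = np.array([s.draw_init(r) for s in model.params])
    xi, _ = model.simulate_forward(theta, r)
    n_checked = 0
    for k in range(40):
        theta_p = theta * (1 + 0.02 * r.standard_normal(len(theta)))
        if not np.isfinite(model.prior_loglik(theta_p)):
            continue
        out = plan.pbp_sweep(0, xi, theta, theta_p, int(r.integers(1 << 31)),
                             0.03)
        if out is None:
            continue
        xi_p, log_corr = out
        d_lat = (model.latent_loglik(theta_p, xi_p)
                 - model.latent_loglik(theta, xi))
        assert log_corr == pytest.approx(-d_lat, abs=1e-7)
        n_checked += 1
    assert n_checked > 20


@pytest.mark.parametrize("bench,param", [("diag_small", "p_D"),
                                         ("svt_small", "mu")])
def test_fast_and_generic_samplers_agree(bench, param, request):
    """Compiled and generic PBP chains target the same posterior."""
    from pbpmc.diagnostics import ess

    _, model, ids = request.getfixturevalue(bench)
    cfg = EngineConfig(updates=4000, burnin=2000, seed=5)
    tf = run_chain(model, ids, cfg, use_fast=True)
    tg = run_chain(model, ids, cfg, use_fast=False)
    a, b = tf.param(param), tg.param(param)
    se = math.sqrt(a.var() / max(ess(a).ess, 2) + b.var() / max(ess(b).ess, 2))
    assert abs(a.mean() - b.mean()) < 5 * se


def test_mbp_runs_on_every_benchmark(request):
    """ID0 is always available and the chain moves."""
    for bench in ("diag_small", "svt_small", "mixed_small",
                  "logistic_small"):
        _, model, _ = request.getfixturevalue(bench)
        cfg = EngineConfig(updates=300, burnin=300, seed=9)
        tr = run_chain(model, make_id0(model), cfg)
        assert tr.counters["pbp"][1] > 0
        assert np.isfinite(tr.logpost).all()


def test_build_svt_from_external_data(rng):
    scn = SvtScenario(E=40)
    data = scn.simulate(rng)["data"]
    model, ids = build_svt(scn, data=data)
    assert model.n_nodes == 40
    assert ids.level == 1
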