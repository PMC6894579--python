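"""Latent-class diagnostic-test model.

A population of P individuals carries a hidden disease status D_e ~
Bernoulli(p_D).  Each individual is tested twice; test t returns positive
with probability Se_t (sensitivity) when infected and negative with
probability Sp_t (specificity) when not.  With no gold standard, two test
results per individual are exactly what makes (p_D, Se, Sp) identifiable.

Because individuals are exchangeable and conditionally independent, the
per-individual ID1 is the *exact* conditional posterior
Pr(D_e = 1 | y_e, theta) by two-point Bayes normalization, and the standard
baseline can Gibbs-sample both the latent statuses and (via beta
conjugacy) the probability parameters.

The label-switching mirror mode (Se <-> 1-Sp, p_D <-> 1-p_D) is removed by
the conventional identifiability constraint Se_t + Sp_t > 1, which can be
disabled for small exactly-enumerable instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from ..dag import DagModel, LatentNode, ObsTerm, ParamSpec
from ..importance import make_id1

__all__ = ["DiagnosticScenario", "build_diagnostic"]


@dataclass
class DiagnosticScenario:
    """Generating scenario: P individuals, prevalence p_D, two tests."""

    P: int = 1000
    p_D: float = 0.5
    se: tuple = (0.6, 0.6)
    sp: tuple = (0.9, 0.9)
    constrain: bool = True     # impose Se_t + Sp_t > 1

    def __post_init__(self):
        probs = (self.p_D, *self.se, *self.sp)
        if not all(0.0 <= q <= 1.0 for q in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def simulate(self, rng: np.random.Generator) -> dict:
        d = (rng.random(self.P) < self.p_D).astype(int)
        ys = {}
        for t in (0, 1):
            prob = np.where(d == 1, self.se[t], 1.0 - self.sp[t])
            ys[f"y{t + 1}"] = (rng.random(self.P) < prob).astype(int)
        data = pd.DataFrame({"individual": np.arange(self.P), **ys})
        truth = pd.DataFrame({"individual": np.arange(self.P), "D": d})
        return {"data": data, "latent_truth": truth}


def _id1_z(theta, y1, y2):
    """Exact Pr(D_e=1 | y_e, theta), vectorized over individuals."""
    p, se1, se2, sp1, sp2 = theta
    w1 = p * (se1 ** y1 * (1 - se1) ** (1 - y1)
              * se2 ** y2 * (1 - se2) ** (1 - y2))
    w0 = (1 - p) * ((1 - sp1) ** y1 * sp1 ** (1 - y1)
                    * (1 - sp2) ** y2 * sp2 ** (1 - y2))
    tot = w1 + w0
    return np.where(tot > 0, w1 / np.where(tot > 0, tot, 1.0), 0.5)


class _DiagnosticPlan:
    """Vectorized sweeps: all individuals are conditionally independent."""

    def __init__(self, y1, y2):
        self.y1 = y1.astype(float)
        self.y2 = y2.astype(float)
        self.P = len(y1)

    def logliks(self, theta, xi):
        p = theta[0]
        se1, se2, sp1, sp2 = theta[1:]
        d = xi
        n1 = float(d.sum())
        n0 = self.P - n1
        lat = xlogy(n1, p) + xlogy(n0, 1 - p)
        s1 = float((d * self.y1).sum())
        s2 = float((d * self.y2).sum())
        m1 = float(((1 - d) * self.y1).sum())
        m2 = float(((1 - d) * self.y2).sum())
        obs = (xlogy(s1, se1) + xlogy(n1 - s1, 1 - se1)
               + xlogy(s2, se2) + xlogy(n1 - s2, 1 - se2)
               + xlogy(m1, 1 - sp1) + xlogy(n0 - m1, sp1)
               + xlogy(m2, 1 - sp2) + xlogy(n0 - m2, sp2))
        return float(lat), float(obs)

    def _z(self, level, theta):
        if level == 0:
            return np.full(self.P, theta[0])
        return _id1_z(theta, self.y1, self.y2)

    def pbp_sweep(self, level, xi, theta_i, theta_p, seed, kappa):
        from .. import kernels

        rng = np.random.default_rng(seed)
        z_i = self._z(level, theta_i)
        z_p = self._z(level, theta_p)
        d_i = xi.astype(np.int64)
        d_p = kernels.propose("bernoulli", {"z": z_i}, {"z": z_p}, d_i, rng)
        log_corr = float(
            (xlogy(d_i, z_i) + xlogy(1 - d_i, 1 - z_i)).sum()
            - (xlogy(d_p, z_p) + xlogy(1 - d_p, 1 - z_p)).sum()
        )
        return d_p.astype(float), log_corr

    def latent_sweep(self, xi, theta, seed, lstep):
        # exact Gibbs draw of every status (valid: independent given theta)
        rng = np.random.default_rng(seed)
        z = _id1_z(theta, self.y1, self.y2)
        d = (rng.random(self.P) < z).astype(float)
        return d, self.P, self.P


def _truncated_beta(a, b, lo, rng):
    """Exact draw from Beta(a, b) conditioned on (lo, 1)."""
    flo = stats.beta.cdf(lo, a, b)
    u = flo + (1.0 - flo) * rng.random()
    return float(np.clip(stats.beta.ppf(u, a, b), lo + 1e-12, 1 - 1e-12))


def build_diagnostic(scn: DiagnosticScenario, data: pd.DataFrame = None,
                     rng: np.random.Generator = None):
    """Build the model (+ exact ID1) for a scenario; simulates data if none given.

    Returns ``(model, ids)`` where ids is the exact per-individual ID1.
    ``make_id0(model)`` gives the MBP variant.  A Gibbs baseline (statuses
    and beta-conjugate parameter draws) is registered for ``ids=None`` runs.
    """
    if data is None:
        if rng is None:
            raise ValueError("need data or an rng to simulate it")
        data = scn.simulate(rng)["data"]
    y1 = data["y1"].to_numpy().astype(int)
    y2 = data["y2"].to_numpy().astype(int)
    P = len(y1)

    def beta_init(lo=0.0, hi=1.0):
        return lambda r: r.uniform(lo + 0.05, hi - 0.05)

    params = [
        ParamSpec("p_D", 0.0, 1.0, sample_init=beta_init()),
        ParamSpec("Se1", 0.0, 1.0, sample_init=beta_init(0.5, 1.0)),
        ParamSpec("Se2", 0.0, 1.0, sample_init=beta_init(0.5, 1.0)),
        ParamSpec("Sp1", 0.0, 1.0, sample_init=beta_init(0.5, 1.0)),
        ParamSpec("Sp2", 0.0, 1.0, sample_init=beta_init(0.5, 1.0)),
    ]

    nodes = [
        LatentNode("bernoulli", lambda xi, th: {"z": th[0]}) for _ in range(P)
    ]

    def obs_logp(e, t):
        def logp(xi, th, y):
            se, sp = th[1 + t], th[3 + t]
            if xi[e] == 1:
                pr = se if y == 1 else 1 - se
            else:
                pr = 1 - sp if y == 1 else sp
            return np.log(pr) if pr > 0 else -np.inf
        return logp

    def obs_sample(e, t):
        def sample(xi, th, r):
            se, sp = th[1 + t], th[3 + t]
            pr = se if xi[e] == 1 else 1 - sp
            return int(r.random() < pr)
        return sample

    obs = []
    for e in range(P):
        for t, y_arr in ((0, y1), (1, y2)):
            obs.append(ObsTerm((e,), obs_logp(e, t),
                               obs_sample(e, t), int(y_arr[e])))

    model = DagModel(params, nodes, obs, name="diagnostic")
    if scn.constrain:
        def extra(th):
            ok = (th[1] + th[3] > 1.0) and (th[2] + th[4] > 1.0)
            return 0.0 if ok else -np.inf
        model.extra_log_prior = extra

    plan = _DiagnosticPlan(y1, y2)
    model.fast_plans = {0: plan, 1: plan, "baseline": plan}

    # conjugate Gibbs draws for the baseline sampler
    def gibbs_p(xi, th, r):
        n1 = float(xi.sum())
        return float(r.beta(1 + n1, 1 + P - n1))

    def gibbs_se(t, y_arr):
        def draw(xi, th, r):
            n1 = float(xi.sum())
            s = float((xi * y_arr).sum())
            if scn.constrain:
                return _truncated_beta(1 + s, 1 + n1 - s, 1 - th[3 + t], r)
            return float(r.beta(1 + s, 1 + n1 - s))
        return draw

    def gibbs_sp(t, y_arr):
        def draw(xi, th, r):
            n0 = float((1 - xi).sum())
            m = float(((1 - xi) * y_arr).sum())
            if scn.constrain:
                return _truncated_beta(1 + n0 - m, 1 + m, 1 - th[1 + t], r)
            return float(r.beta(1 + n0 - m, 1 + m))
        return draw

    model.param_gibbs = {
        "p_D": gibbs_p,
        "Se1": gibbs_se(0, y1), "Se2": gibbs_se(1, y2),
        "Sp1": gibbs_sp(0, y1), "Sp2": gibbs_sp(1, y2),
    }

    return model, make_id1(model)
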