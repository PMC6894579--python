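"""Pedigree-based mixed model (the quantitative-genetics "animal model").

Records y = X beta + Z a + eps decompose each measurement into F fixed
effects, an additive-genetic random effect (breeding value) per individual
with covariance sigma_a^2 A, and iid residuals with variance sigma_e^2.
The heritability-like ratio r^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)
measures the genetic contribution.

Rather than working with the dense multivariate normal, breeding values are
expressed as a DAG via the pedigree: founders a_e ~ N(0, sigma_a^2) and
non-founders a_e ~ N((a_sire + a_dam)/2, sigma_a^2/2) (Mendelian-sampling
variance without inbreeding depression).  The implied covariance is exactly
sigma_a^2 A with A given by the tabular method (see
:func:`relationship_matrix`).

All conditionals and records are normal, so ID1 (own record) and ID2 (own
plus offspring records, each offspring integrated out against its record)
are exact conjugate normal algebra, and the baseline latent sweep is a
Gibbs draw of each breeding value from its full conditional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ..dag import DagModel, LatentNode, ObsTerm, ParamSpec
from ..importance import make_id2

__all__ = ["MixedScenario", "simulate_pedigree", "relationship_matrix",
           "build_mixed"]


def simulate_pedigree(generations: int, per_gen: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Random-mating pedigree: each non-founder gets two distinct parents
    drawn from the previous generation.  ids are 1-based; 0 = unknown."""
    if per_gen < 2:
        raise ValueError("need at least 2 individuals per generation")
    ids, sires, dams = [], [], []
    for g in range(generations):
        start = g * per_gen
        prev = np.arange((g - 1) * per_gen, g * per_gen) + 1
        for k in range(per_gen):
            ids.append(start + k + 1)
            if g == 0:
                sires.append(0)
                dams.append(0)
            else:
                s, d = rng.choice(prev, size=2, replace=False)
                sires.append(int(s))
                dams.append(int(d))
    return pd.DataFrame({"id": ids, "sire": sires, "dam": dams})


def relationship_matrix(ped: pd.DataFrame) -> np.ndarray:
    """Additive relationship matrix implied by the DAG decomposition
    (tabular method; diagonal 1 + 0.5 A[sire, dam] for known parents)."""
    n = len(ped)
    sire = ped["sire"].to_numpy() - 1
    dam = ped["dam"].to_numpy() - 1
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
        a[i, i] = 1.0 + (0.5 * a[s, d] if s >= 0 and d >= 0 else 0.0)
    return a


@dataclass
class MixedScenario:
    """Generating scenario: pedigree shape, variance split and fixed effects."""

    generations: int = 4
    per_gen: int = 1000
    r2: float = 0.5
    var_total: float = 1.0
    beta: tuple = (1.0, 0.5)    # intercept + one binary covariate

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def sigma_a2(self):
        return self.r2 * self.var_total

    @property
    def sigma_e2(self):
        return (1.0 - self.r2) * self.var_total

    def simulate(self, rng: np.random.Generator,
                 pedigree: pd.DataFrame = None) -> dict:
        ped = (pedigree if pedigree is not None
               else simulate_pedigree(self.generations, self.per_gen, rng))
        n = len(ped)
        sire = ped["sire"].to_numpy() - 1
        dam = ped["dam"].to_numpy() - 1
        a = np.zeros(n)
        sa = math.sqrt(self.sigma_a2)
        for i in range(n):
            if sire[i] < 0:
                a[i] = rng.normal(0.0, sa)
            else:
                a[i] = rng.normal(0.5 * (a[sire[i]] + a[dam[i]]),
                                  sa / math.sqrt(2))
        x = rng.integers(0, 2, n).astype(float)
        y = (self.beta[0] + self.beta[1] * x + a
             + rng.normal(0.0, math.sqrt(self.sigma_e2), n))
        data = pd.DataFrame({"individual": ped["id"], "x1": x, "record": y})
        truth = pd.DataFrame({"individual": ped["id"], "a": a})
        return {"data": data, "pedigree": ped, "latent_truth": truth}


# --- compiled sweeps --------------------------------------------------------


@njit(cache=True)
def _mixed_pbp_sweep(level, a_i, th_i, th_p, sire, dam, c2_ptr, c2_child,
                     c2_mate, x, y, seed, kappa):
    np.random.seed(seed)
    n = a_i.shape[0]
    a_p = np.empty(n)
    log_corr = 0.0
    lhalf = 0.5 * math.log(2.0 * math.pi)
    xb_i = th_i[0] + th_i[1] * x
    xb_p = th_p[0] + th_p[1] * x
    for e in range(n):
        m = np.empty(2)
        v = np.empty(2)
        for s in range(2):
            if s == 0:
                a_cur, sa2, se2, xb = a_i, th_i[2], th_i[3], xb_i
            else:
                a_cur, sa2, se2, xb = a_p, th_p[2], th_p[3], xb_p
            if sire[e] < 0:
                m0, v0 = 0.0, sa2
            else:
                m0 = 0.5 * (a_cur[sire[e]] + a_cur[dam[e]])
                v0 = 0.5 * sa2
            if level == 0:
                m[s], v[s] = m0, v0
                continue
            prec = 1.0 / v0 + 1.0 / se2
            num = m0 / v0 + (y[e] - xb[e]) / se2
            if level >= 2:
                tau = 0.25 / (0.5 * sa2 + se2)
                for k in range(c2_ptr[e], c2_ptr[e + 1]):
                    d = c2_child[k]
                    mate = c2_mate[k]
                    num += tau * (2.0 * (y[d] - xb[d]) - a_cur[mate])
                    prec += tau
            m[s] = num / prec
            v[s] = 1.0 / prec
        m_i, v_i, m_p, v_p = m[0], v[0], m[1], v[1]
        if v_p > v_i:
            alpha = math.sqrt(kappa + (1.0 - kappa) * v_p / v_i)
            mean = m_p + alpha * (a_i[e] - m_i)
            var = kappa * (v_p - v_i)
        else:
            alpha = math.sqrt(kappa + (1.0 - kappa) * v_i / v_p)
            mean = m_p + alpha * (v_p / v_i) * (a_i[e] - m_i)
            var = kappa * (v_p / v_i) * (v_i - v_p)
        a_p[e] = mean + (math.sqrt(var) * np.random.standard_normal()
                         if var > 0 else 0.0)
        log_corr += (-lhalf - 0.5 * math.log(v_i)
                     - 0.5 * (a_i[e] - m_i) ** 2 / v_i)
        log_corr -= (-lhalf - 0.5 * math.log(v_p)
                     - 0.5 * (a_p[e] - m_p) ** 2 / v_p)
    return a_p, log_corr


@njit(cache=True)
def _mixed_gibbs_sweep(a, th, sire, dam, g_ptr, g_child, g_mate, x, y, seed):
    np.random.seed(seed)
    n = a.shape[0]
    sa2, se2 = th[2], th[3]
    xb = th[0] + th[1] * x
    for e in range(n):
        if sire[e] < 0:
            prec = 1.0 / sa2
            num = 0.0
        else:
            prec = 2.0 / sa2
            num = (a[sire[e]] + a[dam[e]]) / sa2
        for k in range(g_ptr[e], g_ptr[e + 1]):
            d = g_child[k]
            mate = g_mate[k]
            num += (2.0 * a[d] - a[mate]) / (2.0 * sa2)
            prec += 1.0 / (2.0 * sa2)
        num += (y[e] - xb[e]) / se2
        prec += 1.0 / se2
        a[e] = num / prec + np.random.standard_normal() / math.sqrt(prec)
    return a, n, n


class _MixedPlan:
    def __init__(self, sire, dam, x, y):
        self.sire = sire.astype(np.int64)
        self.dam = dam.astype(np.int64)
        self.x = x.astype(float)
        self.y = y.astype(float)
        n = len(y)
        founders = self.sire < 0
        self.founders = founders
        # children with the co-parent, CSR per parent; c2 keeps only
        # children whose co-parent precedes the parent (valid ID2 terms)
        pairs_all = [[] for _ in range(n)]
        pairs_id2 = [[] for _ in range(n)]
        for d in range(n):
            s, m = self.sire[d], self.dam[d]
            if s < 0:
                continue
            pairs_all[s].append((d, m))
            pairs_all[m].append((d, s))
            later, earlier = (s, m) if s > m else (m, s)
            pairs_id2[later].append((d, earlier))
        def to_csr(pairs):
            ptr = np.zeros(n + 1, dtype=np.int64)
            child, mate = [], []
            for e in range(n):
                ptr[e + 1] = ptr[e] + len(pairs[e])
                for (d, m) in pairs[e]:
                    child.append(d)
                    mate.append(m)
            return ptr, np.array(child, np.int64), np.array(mate, np.int64)
        self.g_ptr, self.g_child, self.g_mate = to_csr(pairs_all)
        self.c2_ptr, self.c2_child, self.c2_mate = to_csr(pairs_id2)

    def logliks(self, theta, xi):
        b0, b1, sa2, se2 = theta
        a = xi
        f = self.founders
        lat = float(np.sum(-0.5 * np.log(2 * np.pi * sa2)
                           - 0.5 * a[f] ** 2 / sa2))
        nf = ~f
        mid = 0.5 * (a[self.sire[nf]] + a[self.dam[nf]])
        lat += float(np.sum(-0.5 * np.log(np.pi * sa2)
                            - (a[nf] - mid) ** 2 / sa2))
        resid = self.y - (b0 + b1 * self.x + a)
        obs = float(np.sum(-0.5 * np.log(2 * np.pi * se2)
                           - 0.5 * resid ** 2 / se2))
        return lat, obs

    def pbp_sweep(self, level, xi, theta_i, theta_p, seed, kappa):
        a_p, log_corr = _mixed_pbp_sweep(
            level, xi, np.asarray(theta_i), np.asarray(theta_p),
            self.sire, self.dam, self.c2_ptr, self.c2_child, self.c2_mate,
            self.x, self.y, seed, kappa)
        if not np.isfinite(log_corr):
            return None
        return a_p, float(log_corr)

    def latent_sweep(self, xi, theta, seed, lstep):
        a, n_acc, n_tot = _mixed_gibbs_sweep(
            xi.copy(), np.asarray(theta), self.sire, self.dam,
            self.g_ptr, self.g_child, self.g_mate, self.x, self.y, seed)
        return a, n_acc, n_tot


def build_mixed(scn: MixedScenario, data: pd.DataFrame = None,
                pedigree: pd.DataFrame = None,
                rng: np.random.Generator = None):
    """Build the animal model and its exact ID2 for given (or simulated) data."""
    if data is None:
        if rng is None:
            raise ValueError("need data or an rng to simulate it")
        sim = scn.simulate(rng, pedigree)
        data, pedigree = sim["data"], sim["pedigree"]
    if pedigree is None:
        raise ValueError("a pedigree table is required with external data")
    sire = pedigree["sire"].to_numpy().astype(int) - 1
    dam = pedigree["dam"].to_numpy().astype(int) - 1
    if np.any((sire >= np.arange(len(sire))) & (sire >= 0)) or np.any(
            (dam >= np.arange(len(dam))) & (dam >= 0)):
        raise ValueError("pedigree must list parents before offspring")
    x = data["x1"].to_numpy().astype(float)
    y = data["record"].to_numpy().astype(float)
    n = len(y)

    vy = float(np.var(y))
    params = [
        ParamSpec("beta0", sample_init=lambda r: r.normal(np.mean(y),
                                                          np.std(y))),
        ParamSpec("beta1", sample_init=lambda r: r.normal(0, max(np.std(y), 1))),
        ParamSpec("sigma_a2", 0.0, np.inf,
                  sample_init=lambda r: vy * r.uniform(0.2, 0.8)),
        ParamSpec("sigma_e2", 0.0, np.inf,
                  sample_init=lambda r: vy * r.uniform(0.2, 0.8)),
    ]

    def node(e):
        s, d = sire[e], dam[e]
        if s < 0:
            return LatentNode("normal", lambda xi, th: {"mu": 0.0,
                                                        "var": th[2]})
        return LatentNode(
            "normal",
            lambda xi, th, s=s, d=d: {"mu": 0.5 * (xi[s] + xi[d]),
                                      "var": 0.5 * th[2]},
            parents=(min(s, d), max(s, d)),
        )

    def obs_logp(e):
        def logp(xi, th, yv):
            mean = th[0] + th[1] * x[e] + xi[e]
            return (-0.5 * math.log(2 * math.pi * th[3])
                    - 0.5 * (yv - mean) ** 2 / th[3])
        return logp

    def obs_sample(e):
        def sample(xi, th, r):
            return (th[0] + th[1] * x[e] + xi[e]
                    + r.normal(0.0, math.sqrt(th[3])))
        return sample

    nodes = [node(e) for e in range(n)]
    obs = [ObsTerm((e,), obs_logp(e), obs_sample(e), float(y[e]))
           for e in range(n)]
    model = DagModel(params, nodes, obs, name="mixed")
    plan = _MixedPlan(sire, dam, x, y)
    model.fast_plans = {0: plan, 1: plan, 2: plan, "baseline": plan}
    return model, make_id2(model)
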