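"""Importance distributions: per-node approximations to the conditional
posterior pi(xi_e | xi_{e'<e}, theta, y).

Three levels are provided.  ID0 is the model conditional itself (data
ignored); proposals built on it are model-based proposals and need no
hand-tuning.  ID1 multiplies in the observation terms attached to node e,
either exactly (Bernoulli nodes: two-point Bayes normalization; normal nodes
with quadratic observation log-density) or by a Laplace-style quadratic
expansion of the observation log-density (normal nodes, general case).  ID2
additionally folds in each child node's observation by analytically
integrating the child out — implemented for normal nodes whose children are
normal with conditional mean affine in xi_e, which covers pedigree-based
mixed models and normal chains.

Accuracy of an ID only affects proposal efficiency, never correctness: the
Metropolis–Hastings correction uses the same ID densities for the initial
and proposed states, so any ID that is a function of (xi_{e'<e}, theta, y)
leaves the posterior exact.  For that reason ID2 skips children one of whose
other parents has an index above e (their records instead inform that later
parent), keeping the ID a valid function of the preceding latent values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List

import numpy as np

from .dag import DagModel

__all__ = ["IdSpec", "make_id0", "make_id1", "make_id2"]


@dataclass
class IdSpec:
    """Per-node importance-distribution family and parameter map.

    ``params(e, xi, theta)`` returns the characteristic parameter dict of
    ``families[e]`` and may read only ``xi[e'] for e' < e`` (plus theta and
    the observations captured at construction time).
    """

    level: int
    families: List[str]
    params: Callable[[int, np.ndarray, np.ndarray], dict]


def make_id0(model: DagModel) -> IdSpec:
    """The model conditionals themselves; proposals with this spec are MBPs."""
    families = [node.family for node in model.nodes]

    def params(e, xi, theta):
        return model.nodes[e].cond_params(xi, theta)

    return IdSpec(level=0, families=families, params=params)


def _obs_logp_at(model, e, xi, theta, value):
    """Sum of node-e observation terms evaluated with xi_e set to `value`."""
    old = xi[e]
    xi[e] = value
    total = 0.0
    for r in model.obs_by_node[e]:
        term = model.obs[r]
        total += float(term.logp(xi, theta, term.value))
    xi[e] = old
    return total


def _gauss_obs_summary(model, e, xi, theta, x0, scale):
    """Quadratic (Laplace) summary of node-e observation terms around x0.

    Returns (pseudo-observation, pseudo-variance) of an equivalent Gaussian
    likelihood, or None when the local curvature carries no information.
    """
    h = max(1e-5, 1e-4 * scale)
    l0 = _obs_logp_at(model, e, xi, theta, x0)
    lp = _obs_logp_at(model, e, xi, theta, x0 + h)
    lm = _obs_logp_at(model, e, xi, theta, x0 - h)
    grad = (lp - lm) / (2 * h)
    curv = (lp - 2 * l0 + lm) / (h * h)
    if not np.isfinite(grad) or not np.isfinite(curv) or curv >= -1e-12:
        return None
    prec = -curv
    return x0 + grad / prec, 1.0 / prec


def make_id1(model: DagModel) -> IdSpec:
    """Model conditional times the node's own observation terms.

    Observations must already be bound to the model.  Nodes without attached
    observations fall back to ID0.  A builder may register a bespoke rule via
    ``model.id1_rules`` (same signature as ``IdSpec.params``); otherwise
    Bernoulli nodes use the exact two-point posterior and normal nodes a
    quadratic expansion with one Newton refinement of the expansion point.
    """
    families = [node.family for node in model.nodes]
    custom = model.id1_rules

    def params(e, xi, theta):
        if custom is not None:
            out = custom(e, xi, theta)
            if out is not None:
                return out
        node = model.nodes[e]
        base = node.cond_params(xi, theta)
        if not model.obs_by_node[e]:
            return base
        if node.family == "bernoulli":
            l1 = _obs_logp_at(model, e, xi, theta, 1)
            l0 = _obs_logp_at(model, e, xi, theta, 0)
            z0 = base["z"]
            w1 = math.log(z0) + l1 if z0 > 0 else -np.inf
            w0 = math.log1p(-z0) + l0 if z0 < 1 else -np.inf
            m = max(w1, w0)
            z = math.exp(w1 - m) / (math.exp(w1 - m) + math.exp(w0 - m))
            return {"z": z}
        if node.family == "normal":
            mu0, var0 = base["mu"], base["var"]
            sd0 = math.sqrt(var0)
            summ = _gauss_obs_summary(model, e, xi, theta, mu0, sd0)
            if summ is None:
                # no curvature: shift the mean along the local gradient only
                h = max(1e-5, 1e-4 * sd0)
                grad = (_obs_logp_at(model, e, xi, theta, mu0 + h)
                        - _obs_logp_at(model, e, xi, theta, mu0 - h)) / (2 * h)
                if not np.isfinite(grad):
                    return base
                return {"mu": mu0 + var0 * grad, "var": var0}
            ystar, v = summ
            mu1 = (mu0 / var0 + ystar / v) / (1 / var0 + 1 / v)
            # one Newton refinement: re-expand around the first-pass mean
            summ2 = _gauss_obs_summary(model, e, xi, theta, mu1, sd0)
            if summ2 is not None:
                ystar, v = summ2
            prec = 1 / var0 + 1 / v
            return {"mu": (mu0 / var0 + ystar / v) / prec, "var": 1 / prec}
        raise NotImplementedError(
            f"no ID1 rule for family {node.family!r} with observations; "
            "register model.id1_rules or use ID0"
        )

    return IdSpec(level=1, families=families, params=params)


def make_id2(model: DagModel) -> IdSpec:
    """ID1 augmented with analytically integrated child observations.

    Only normal nodes with normal children (conditional mean affine in
    xi_e, variance free of it) are supported; anything else raises,
    directing the user to ID1.  Children with a not-yet-proposed co-parent
    (index above e) are skipped, see module docstring.
    """
    for e, node in enumerate(model.nodes):
        for d in model.children[e]:
            if model.nodes[d].family != "normal" or node.family != "normal":
                raise NotImplementedError(
                    "ID2 is implemented for normal nodes with normal "
                    "children only; use make_id1 instead"
                )
    id1 = make_id1(model)
    custom = model.id2_rules

    def params(e, xi, theta):
        if custom is not None:
            out = custom(e, xi, theta)
            if out is not None:
                return out
        base = id1.params(e, xi, theta)
        node = model.nodes[e]
        if node.family != "normal" or not model.children[e]:
            return base
        mu, var = base["mu"], base["var"]
        prec, pm = 1.0 / var, mu / var
        x_old = xi[e]
        for d in model.children[e]:
            child = model.nodes[d]
            if any(p > e for p in child.parents) or not model.obs_by_node[d]:
                continue
            # slope/intercept of the child's conditional mean in xi_e
            xi[e] = mu
            cp0 = child.cond_params(xi, theta)
            xi[e] = mu + 1.0
            cp1 = child.cond_params(xi, theta)
            xi[e] = x_old
            b = cp1["mu"] - cp0["mu"]
            if abs(b) < 1e-12:
                continue
            a = cp0["mu"] - b * mu
            summ = _gauss_obs_summary(model, d, xi, theta, cp0["mu"],
                                      math.sqrt(cp0["var"]))
            if summ is None:
                continue
            ystar, v = summ
            tau = b * b / (cp0["var"] + v)
            prec += tau
            pm += tau * (ystar - a) / b
        return {"mu": pm / prec, "var": 1.0 / prec}

    return IdSpec(level=2, families=[n.family for n in model.nodes],
                  params=params)
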