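"""Benchmark models: builders, synthetic-data simulators and fast plans.

Four model types spanning the main regimes joint parameter/latent proposals
are designed for: a latent-class diagnostic-test model (discrete latents,
exact ID1), a Student-t stochastic-volatility model (long AR(1) chain,
Laplace ID1), a pedigree-based quantitative-genetics mixed model (normal
conjugacy through ID2) and a tau-leaping logistic birth-death population
model (count latents, ID0 / model-based proposals).
"""

from .diagnostic import DiagnosticScenario, build_diagnostic
from .logistic import LogisticScenario, build_logistic
from .mixed import (
    MixedScenario,
    build_mixed,
    relationship_matrix,
    simulate_pedigree,
)
from .svt import SvtScenario, build_svt

__all__ = [
    "DiagnosticScenario",
    "SvtScenario",
    "MixedScenario",
    "LogisticScenario",
    "build_diagnostic",
    "build_svt",
    "build_mixed",
    "build_logistic",
    "simulate_pedigree",
    "relationship_matrix",
    "simulate_scenario",
]


def simulate_scenario(scenario, rng):
    """Simulate tidy data tables (and true latents) for any scenario."""
    return scenario.simulate(rng)
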