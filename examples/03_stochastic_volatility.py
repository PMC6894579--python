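"""Fit the Student-t stochastic-volatility model to simulated returns.

One thousand days of log-returns are generated from the SVt model with a
highly persistent latent log-volatility (phi = 0.99).  Joint proposals
regenerate the whole volatility path alongside the parameter move, which
is what keeps the chain mixing despite the strong coupling between the
path and (mu, phi, sigma2).
"""

import numpy as np

from pbpmc import EngineConfig, run_chain, summarize
from pbpmc.benchmarks import SvtScenario, build_svt

scn = SvtScenario(E=1000)
model, ids = build_svt(scn, rng=np.random.default_rng(2))
cfg = EngineConfig(updates=20_000, burnin=8_000, seed=2)
trace = run_chain(model, ids, cfg)

print(summarize(trace).round(4))
print(f"\ngenerating values: mu={scn.mu}, phi={scn.phi}, "
      f"sigma2={scn.sigma2}, nu={scn.nu}")
print("mu and sigma2 are well identified from 1000 days; the tail "
      "parameter nu needs far longer series.")
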