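import numpy as np
import pytest

from pbpmc.benchmarks import (
    DiagnosticScenario,
    LogisticScenario,
    MixedScenario,
    SvtScenario,
    build_diagnostic,
    build_logistic,
    build_mixed,
    build_svt,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def diag_small():
    scn = DiagnosticScenario(P=40)
    model, ids = build_diagnostic(scn, rng=np.random.default_rng(11))
    return scn, model, ids


@pytest.fixture(scope="session")
def svt_small():
    scn = SvtScenario(E=60)
    model, ids = build_svt(scn, rng=np.random.default_rng(12))
    return scn, model, ids


@pytest.fixture(scope="session")
def mixed_small():
    scn = MixedScenario(generations=3, per_gen=20)
    model, ids = build_mixed(scn, rng=np.random.default_rng(13))
    return scn, model, ids


@pytest.fixture(scope="session")
def logistic_small():
    scn = LogisticScenario(T=41, M=5, P0=8)
    model, ids = build_logistic(scn, rng=np.random.default_rng(14))
    return scn, model, ids
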