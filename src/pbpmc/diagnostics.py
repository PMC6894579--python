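"""Chain diagnostics: effective sample size and posterior summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trace

__all__ = ["EssResult", "ess", "summarize"]


@dataclass(frozen=True)
class EssResult:
    """Effective sample size and the autocorrelation lag cutoff used."""

    ess: float
    cutoff: int


def _autocov(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    return acov


def ess(samples) -> EssResult:
    """Effective sample size via Geyer's initial-positive-sequence rule.

    ESS = N / (1 + 2 sum_k rho_k) with the autocorrelation sum truncated at
    the last strictly positive pair sum rho_{2k} + rho_{2k+1}.  Values above
    N (antithetic chains) are capped at N with a warning, as is a constant
    series.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("ess expects a 1-d sample sequence")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    acov = _autocov(x)
    if acov[0] <= 0:
        warnings.warn("constant series: reporting ESS = N", stacklevel=2)
        return EssResult(float(n), 0)
    rho = acov / acov[0]
    tau = -1.0
    cutoff = 0
    for k in range(0, (n - 1) // 2):
        pair = rho[2 * k] + rho[2 * k + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        cutoff = 2 * k + 1
    out = n / tau if tau > 0 else float("inf")
    if out > n:
        warnings.warn("ESS above N (antithetic chain): capping at N",
                      stacklevel=2)
        out = float(n)
    return EssResult(float(out), cutoff)


def summarize(trace: Trace) -> pd.DataFrame:
    """Per-parameter posterior summary table.

    Columns: mean, sd, 2.5/50/97.5 percentiles and ESS; chain-level
    acceptance rates are attached as ``DataFrame.attrs['acceptance']``.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    rows = []
    for k, name in enumerate(trace.param_names):
        x = trace.thetas[:, k]
        q = np.percentile(x, [2.5, 50.0, 97.5])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = ess(x).ess
        rows.append({"param": name, "mean": x.mean(), "sd": x.std(ddof=1),
                     "q2.5": q[0], "median": q[1], "q97.5": q[2], "ess": e})
    df = pd.DataFrame(rows).set_index("param")
    df.attrs["acceptance"] = {k: trace.acceptance(k)
                              for k in trace.counters}
    return df
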