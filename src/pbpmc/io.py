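"""Run configuration and trace input/output.

Configs are TOML or JSON files with optional ``scenario`` and ``engine``
tables plus top-level ``id_level``/``baseline`` switches; traces are plain
CSV (one row per retained update) with a JSON metadata sidecar carrying the
seed, the echoed configuration and acceptance summaries — enough to replay
the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import EngineConfig, Trace

__all__ = ["RunConfig", "load_config", "save_trace", "load_trace",
           "save_metadata"]


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration for a benchmark."""

    benchmark: str
    scenario: dict
    engine: dict
    id_level: int = None
    baseline: bool = False
    seed: int = 0

    def engine_config(self, seed=None) -> EngineConfig:
        kw = dict(self.engine)
        kw["seed"] = self.seed if seed is None else seed
        return EngineConfig(**kw)


_TOP_KEYS = {"scenario", "engine", "id_level", "baseline", "seed"}


def load_config(path, benchmark: str, seed: int = 0) -> RunConfig:
    """Read and validate a TOML/JSON config; raise KeyError on bad keys."""
    if path is None:
        raw = {}
    else:
        text = Path(path).read_bytes()
        if str(path).endswith(".json"):
            raw = json.loads(text)
        else:
            raw = tomllib.loads(text.decode())
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise KeyError(f"unknown config key {sorted(unknown)[0]!r}")
    for section in ("scenario", "engine"):
        if path is not None and section not in raw:
            raise KeyError(f"missing config key {section!r}")
    engine = dict(raw.get("engine", {}))
    valid_engine = {f.name for f in dataclasses.fields(EngineConfig)}
    for key in engine:
        if key not in valid_engine:
            raise KeyError(f"unknown engine config key {key!r}")
    return RunConfig(
        benchmark=benchmark,
        scenario=dict(raw.get("scenario", {})),
        engine=engine,
        id_level=raw.get("id_level"),
        baseline=bool(raw.get("baseline", False)),
        seed=int(raw.get("seed", seed)),
    )


def save_trace(trace: Trace, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    trace.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def load_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def save_metadata(path, trace: Trace, config: RunConfig = None) -> None:
    meta = {
        "acceptance": {k: trace.acceptance(k) for k in trace.counters},
        "counters": {k: list(v) for k, v in trace.counters.items()},
        "j_final": trace.j_final,
        "sigma_final": np.asarray(trace.sigma_final).tolist()
        if trace.sigma_final is not None else None,
        "n_samples": len(trace),
        "param_names": trace.param_names,
    }
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    Path(path).write_text(json.dumps(meta, indent=2, default=float))
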