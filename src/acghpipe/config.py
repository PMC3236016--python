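"""One structured config governing every pipeline stage.

All thresholds default to the published values; everything else defaults
to the package's documented choices. A YAML file may override any subset
of keys; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .preprocess import QcThresholds, Thresholds
from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    thresholds: Thresholds = field(default_factory=Thresholds)
    normalize_method: str = "block_median"
    lowess_span: float = 0.3
    k_max: int = 5
    n_restarts: int = 5
    hmm_max_iter: int = 500
    hmm_tol: float = 1e-6
    smooth_lambda: float = 0.1
    merge_tol: float = 0.1
    region_rule: str = "majority"
    cluster_metric: str = "hamming"
    cluster_linkage: str = "average"
    cluster_k: int = 5
    region_test: str = "fisher"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        nested = {"simulation": SimulationConfig, "qc": QcThresholds, "thresholds": Thresholds}
        for key, value in raw.items():
            if key in nested:
                known = {f.name for f in dataclasses.fields(nested[key])}
                extra = set(value) - known
                if extra:
                    raise ConfigError(f"unknown keys under {key}: {sorted(extra)}")
                setattr(cfg, key, nested[key](**value))
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        sim = out["simulation"]
        if sim.get("alteration_spec"):
            sim["alteration_spec"] = [dict(a) for a in sim["alteration_spec"]]
        return out

    def echo_json(self, path: str | Path) -> None:
        """Write the fully resolved config next to a run's outputs."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
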