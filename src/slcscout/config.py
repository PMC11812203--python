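"""Run configuration, provenance headers and parameter files.

A run is described by one declarative YAML file (paths, score
parameters, evaluation and drug settings, seed); command-line flags
override file values.  Every output table carries a provenance comment
header recording the package version, the root seed and a hash of the
effective parameters, so a result file can be traced back to the exact
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .data_model import ValidationError
from .scoring import ScoreParams


@dataclass
class RunConfig:
    """Effective settings of one CLI invocation."""

    seed: int = 0
    outdir: str = "slcscout_out"
    params: ScoreParams = field(default_factory=ScoreParams)
    min_overlap: int = 10
    n_random_tables: int = 100
    bootstrap_b: int = 100
    split: float = 0.7
    iters: int = 10
    drug_frac: float = 0.2
    drug_n_iter: int = 100
    drug_top_n: int = 50
    max_degree: int | None = None
    exclude_metabolites: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def params_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self, version: str) -> list[str]:
        return [
            f"slcscout {version}",
            f"seed={self.seed}",
            f"params_hash={self.params_hash()}",
            f"config={json.dumps(self.to_dict(), sort_keys=True, default=str)}",
        ]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Overrides with value ``None`` are ignored, so CLI flags only take
    effect when given.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        data.update(raw)
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    params_data = data.pop("params", None)
    cfg = RunConfig(**{k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__})
    if params_data:
        cfg.params = ScoreParams(**params_data)
    return cfg


def parse_provenance(comments: list[str]) -> dict:
    """Recover the configuration dictionary from a provenance header."""
    for line in comments:
        if line.startswith("config="):
            return json.loads(line[len("config="):])
    raise ValidationError("no config line in provenance header")
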