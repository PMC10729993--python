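"""Declarative run configuration with strict validation and seed fan-out.

A run is described by a YAML/JSON document with per-command blocks.  Unknown
keys are rejected; every violation is reported (pydantic collects them all,
not just the first).  One global seed fans out into named child streams so
the subsystems (sampling, training, splits, dynamics) are independently
reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthBlock(_Block):
    L: int = Field(300, ge=2)
    q: int = Field(21, ge=2)
    M: int = Field(50, ge=1)
    n_sequences: int = Field(500, ge=1)
    coupling_scale: float = Field(1.0, ge=0)
    labeled_fraction: float = Field(0.15, gt=0, le=1)
    label_noise: float = Field(0.1, ge=0, le=0.5)
    burn_in: int = Field(300, ge=0)
    thinning: int = Field(10, ge=1)


class TrainBlock(_Block):
    hidden_units: int = Field(200, ge=1)
    epochs: int = Field(100, ge=1)
    batch_size: int = Field(128, ge=1)
    learning_rate: float = Field(5e-4, gt=0)
    weight_decay: float = Field(1e-4, ge=0)
    n_chains: int = Field(100, ge=1)
    gibbs_steps: int = Field(10, ge=1)
    gamma: float = Field(0.0, ge=0)
    validation_fraction: float = Field(0.10, gt=0, lt=1)
    similarity_threshold: float = Field(0.9, gt=0, le=1)


class SweepBlock(_Block):
    gammas: list[float] = Field(default_factory=lambda: [0.0, 0.1, 1.0, 10.0,
                                                         100.0])


class CriterionBlock(_Block):
    kind: str
    role: str = "constraint"
    statistic: str | None = None
    bounds: tuple[float, float] | None = None
    threshold: float | None = None
    horizon: int = Field(100, ge=1)


class SampleBlock(_Block):
    alpha: float = Field(1e-2, gt=0)
    eps: float = Field(0.1, ge=0)
    lam: float = Field(1e-2, ge=0)
    n_samples: int = Field(200, ge=2)
    n_steps: int = Field(200, ge=1)
    n_chains: int = Field(10, ge=1)
    decode: str = Field("sample", pattern="^(sample|argmax)$")
    checkpoint_every: int = Field(0, ge=0)
    criteria: list[CriterionBlock] = Field(default_factory=list)


class ScoreBlock(_Block):
    motif_query: str = "NGG"
    score_method: str = Field("product", pattern="^(product|mean_log)$")


class EvalBlock(_Block):
    activity_threshold: float = 0.5
    inactive_threshold: float = 0.2
    min_support: int = Field(5, ge=1)


class RunConfig(_Block):
    seed: int = Field(0, ge=0, lt=2 ** 31)
    outdir: str = "runs"
    log_level: str = Field("INFO", pattern="^(DEBUG|INFO|WARNING|ERROR)$")
    synth: SynthBlock = Field(default_factory=SynthBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    sample: SampleBlock = Field(default_factory=SampleBlock)
    score: ScoreBlock = Field(default_factory=ScoreBlock)
    eval: EvalBlock = Field(default_factory=EvalBlock)


def resolve_config(document: dict | None) -> RunConfig:
    """Validate a config document, filling defaults; idempotent.

    Raises :class:`ConfigError` listing every type/range violation.
    """
    try:
        return RunConfig.model_validate(document or {})
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) \
            from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    return resolve_config(doc)


def persist_config(cfg: RunConfig, outdir) -> Path:
    """Write the resolved config (and tool version) next to the outputs."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.json"
    doc = cfg.model_dump()
    doc["_tool_version"] = __version__
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def seed_stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream from the global seed."""
    salt = int.from_bytes(name.encode(), "little") % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def child_seed(seed: int, name: str) -> int:
    salt = int.from_bytes(name.encode(), "little") % (2 ** 31)
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0]
               % (2 ** 31))
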