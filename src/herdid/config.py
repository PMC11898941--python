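"""Run configuration: schema-validated YAML/JSON blocks for the CLI.

Unknown keys are rejected so typos fail loudly, and the fully resolved
configuration (plus its hash) is embedded in every report for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import ValidationError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LossBlock(_Strict):
    margin_deg: float = 28.6
    scale: float = 64.0
    num_subcenters: int = 3
    lambda_arcface: float = 1.0
    lambda_center: float = 0.5
    center_reduction: str = "sum"


class HeadBlock(_Strict):
    in_dim: int = 768
    hidden_dim: int = 512
    out_dim: int = 64
    dropout_rate: float = 0.2


class TrainBlock(_Strict):
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-5
    lr_decay_every: int = 0
    lr_decay_factor: float = 0.5


class PolicyBlock(_Strict):
    # no default threshold: the operating point is dataset-dependent and must
    # be chosen (e.g. by the F1-Open sweep)
    threshold: float | None = None
    aggregation: str = "max"


class ProtocolBlock(_Strict):
    level: str = "embedding"            # "embedding" | "image"
    known_identities: int = 8
    unknown_identities: int = 3
    gallery_per_identity: int = 10
    train_per_identity: int = 30
    test_per_identity: int = 10
    dim: int = 64
    kappa: float = 50.0
    min_angle_deg: float = 25.0
    canvas: int = 48


class PathsBlock(_Strict):
    data: str | None = None
    gallery: str | None = None
    model: str | None = None
    reports: str = "reports"


class RunConfig(_Strict):
    paths: PathsBlock = Field(default_factory=PathsBlock)
    loss: LossBlock = Field(default_factory=LossBlock)
    head: HeadBlock = Field(default_factory=HeadBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    policy: PolicyBlock = Field(default_factory=PolicyBlock)
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML or JSON config file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse config {path}: {exc}") from exc
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ValidationError(f"invalid config {path}: {exc}") from exc
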