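"""Run configuration: every tunable with defaults, validated with field paths.

Unknown keys are rejected; cross-field rules (query size divisible by the
class count under balanced sampling, positive learning rates, thresholds in
(0, 1]) are enforced at construction.  An empty YAML file yields the
all-defaults configuration.
"""

from __future__ import annotations

import logging
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .data_io import ConfigurationError

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """All tunables of a meta-learning run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # episodes
    n_shot: int = Field(10, ge=1, description="support-set size N (total, not per class)")
    m_query: int = Field(16, ge=1, description="query-set size M")
    n_classes: int = Field(2, ge=2)
    balanced_query: bool = True  # the query-balancing (QB) switch
    support_per_class: bool = False  # alternative N-per-class reading of N-shot
    frozen_split: bool = False  # reuse one support/query draw per task across epochs
    balanced_fallback: Literal["skip", "replacement"] = "skip"

    # losses
    use_br: bool = True
    use_avuc: bool = True
    lambda0: float = Field(0.01, ge=0.0, le=1.0, description="annealing floor")
    avuc_u_threshold: float = Field(0.5, gt=0.0, lt=1.0)

    # optimization
    inner_lr: float = Field(0.01, gt=0.0)
    outer_lr: float = Field(0.005, gt=0.0)
    inner_steps_train: int = Field(1, ge=0)
    inner_steps_test: int = Field(5, ge=0)
    epochs: int = Field(30, ge=0)
    order: Literal["first", "second"] = "second"
    outer_optimizer: Literal["adam", "sgd"] = "adam"
    grad_clip: float = Field(50.0, ge=0.0, description="meta-gradient norm clip; 0 disables")
    tasks_per_batch: Optional[int] = Field(None, ge=1)
    freeze_encoder: bool = False

    # encoder
    n_layers: int = Field(3, ge=1)
    embedding_dim: int = Field(64, ge=1)
    atom_vocab: tuple[int, ...] = (8, 3)
    bond_vocab: Optional[tuple[int, ...]] = None
    learn_epsilon: bool = False

    # data / reporting
    n_train_tasks: int = Field(4, ge=1)
    n_test_tasks: int = Field(2, ge=1)
    seed: int = 0
    uncertainty_threshold: float = Field(0.5, gt=0.0, le=1.0)
    report_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 1.0)

    @model_validator(mode="after")
    def _cross_field(self) -> "RunConfig":
        if self.balanced_query and self.m_query % self.n_classes:
            raise ValueError(
                f"m_query={self.m_query} must be divisible by n_classes="
                f"{self.n_classes} when balanced_query is on"
            )
        for t in self.report_thresholds:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"report threshold {t} outside (0, 1]")
        if self.lambda0 == 0.0:
            logger.warning("lambda0=0: both regularizers start at zero weight")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**(raw or {}))
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def validate_config(raw: Optional[dict]) -> RunConfig:
    """Build a :class:`RunConfig` from a raw mapping, reporting field paths on error."""
    try:
        return RunConfig(**(raw or {}))
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
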