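"""One structured YAML config bundling every tunable of the pipeline.

All defaults are echoed into the run log on load so a processing run is
auditable even when no config file is given.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .daily_metrics import GoalSet, ThresholdConfig
from .minute_features import Demographics, EnergyModel, PushDetectorConfig

__all__ = ["ProcessingConfig", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProcessingConfig:
    wheel_diameter_m: float = 0.6
    demographics: Demographics = field(default_factory=lambda: Demographics(mass_kg=75.0))
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    push_detector: PushDetectorConfig = field(default_factory=PushDetectorConfig)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    goals: GoalSet = field(default_factory=GoalSet)
    break_rule: str = "nonsedentary"
    coverage_floor: float = 0.30

    def __post_init__(self) -> None:
        if self.wheel_diameter_m <= 0:
            raise ValueError("wheel diameter must be positive")
        if not 0 < self.coverage_floor <= 1:
            raise ValueError("coverage floor must lie in (0, 1]")
        if self.break_rule not in ("nonsedentary", "mvpa_only"):
            raise ValueError("break_rule must be 'nonsedentary' or 'mvpa_only'")


_SECTIONS = {
    "demographics": Demographics,
    "thresholds": ThresholdConfig,
    "push_detector": PushDetectorConfig,
    "energy_model": EnergyModel,
    "goals": GoalSet,
}


def load_config(path: str | Path | None = None) -> ProcessingConfig:
    """Load a YAML config; missing keys fall back to documented defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](**value)
        else:
            kwargs[key] = value
    cfg = ProcessingConfig(**kwargs)
    logger.info("effective processing config: %s", dataclasses.asdict(cfg))
    return cfg
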