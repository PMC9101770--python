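"""Run configuration: a single YAML file with validated defaults.

All defaults are documented here: window h = 50 samples (0.5 s at 100 Hz),
5 CV folds, test fraction 0.25, full per-family classifier grids, smoothing
grids τ ∈ 0:0.05:3 s and η ∈ 0.05:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .features import DEFAULT_WINDOW
from .io import SensorLogDialect
from .pipeline import FAMILIES, SplitPlan
from .simulate import TrialRecipe


class ConfigError(ValueError):
    """The configuration file violates the schema."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, reproducible from config + seed."""

    seed: int = 0
    window: int = DEFAULT_WINDOW
    family: str = "decision_tree"
    grid: dict = field(default_factory=dict)
    test_fraction: float = 0.25
    cv_folds: int = 5
    n_trials: int = 28
    n_subjects: int = 3
    preset: str = "easy"
    change_margin: int = 12
    tau_grid: Optional[list] = None
    eta_grid: Optional[list] = None
    dialect: SensorLogDialect = field(default_factory=SensorLogDialect)
    recipe: Optional[TrialRecipe] = None

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ConfigError("window must be non-negative")
        if self.family not in FAMILIES:
            raise ConfigError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be ≥ 2")
        if self.n_trials < self.n_subjects or self.n_subjects < 1:
            raise ConfigError("need n_trials ≥ n_subjects ≥ 1")
        if self.change_margin < 0:
            raise ConfigError("change_margin must be non-negative")

    @property
    def split_plan(self) -> SplitPlan:
        return SplitPlan(
            test_fraction=self.test_fraction, cv_folds=self.cv_folds, seed=self.seed
        )


_KNOWN_KEYS = {
    "seed",
    "window",
    "family",
    "grid",
    "test_fraction",
    "cv_folds",
    "n_trials",
    "n_subjects",
    "preset",
    "change_margin",
    "tau_grid",
    "eta_grid",
    "dialect",
    "recipe",
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        if "dialect" in raw:
            raw["dialect"] = SensorLogDialect(**raw["dialect"])
        if "recipe" in raw and raw["recipe"] is not None:
            recipe = dict(raw["recipe"])
            if "activity_schedule" in recipe:
                recipe["activity_schedule"] = [
                    (str(k), float(d)) for k, d in recipe["activity_schedule"]
                ]
            raw["recipe"] = TrialRecipe(**recipe)
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: RunConfig, path) -> None:
    """Serialize a config back to YAML (for run provenance)."""
    data = asdict(config)
    if config.recipe is not None:
        data["recipe"]["activity_schedule"] = [
            [k, d] for k, d in config.recipe.activity_schedule
        ]
    data["dialect"]["quaternion_columns"] = list(config.dialect.quaternion_columns)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
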