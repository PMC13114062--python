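"""Schema-validated pipeline configuration (YAML-loadable).

One top-level ``seed`` fans out deterministically to every stochastic
stage; unknown keys are rejected so typos fail fast, before any compute.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .modeling import MODEL_NAMES
from .selection import GAConfig
from .synthetic import ClassEffect, SynthConfig, effects_from_dict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    n_subjects_pos: int = 34
    n_subjects_neg: int = 30
    channels: list[str] = ["Fp1", "Fz", "Fp2"]
    fs: float = 256.0
    duration_s: float = 300.0
    effect: dict[str, dict] | None = None  # per-class generator overrides
    null: bool = False                     # identical classes (calibration)


class GASection(_Strict):
    population_size: int = 50
    generations: int = 20
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism_count: int = 1
    fitness_cv_folds: int = 5
    rf_trees: int = 100
    parsimony_weight: float = 0.01
    init_prob_range: tuple[float, float] = (0.2, 0.8)
    tournament_size: int = 3
    adaptive_mutation: bool = False


class PipelineConfig(_Strict):
    """Everything a run needs; fully determines every output."""

    seed: int = 0
    synthetic: SynthSection | None = None
    manifest: str | None = None            # alternative: cohort on disk
    channels: list[str] = ["Fp1", "Fz", "Fp2"]
    low_hz: float = 0.1
    high_hz: float = 45.0
    denoise: bool = True
    window_s: float = 4.0
    step_s: float = 2.0
    tau: float = 0.95
    selector: str = "rs+ga"
    target_size: int | None = None
    ga: GASection = Field(default_factory=GASection)
    models: list[str] = list(MODEL_NAMES)
    cv_folds: int = 10
    outdir: str = "eegsift-out"

    def validate_semantics(self) -> None:
        if self.synthetic is None and self.manifest is None:
            raise ConfigError("config needs either a 'synthetic' section or a 'manifest'")
        if self.selector not in ("rs+ga", "rank", "aco", "lasso", "pca", "none"):
            raise ConfigError(f"unknown selector {self.selector!r}")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise ConfigError(f"unknown model {m!r}")

    def synth_config(self) -> SynthConfig:
        if self.synthetic is None:
            raise ConfigError("no synthetic section in config")
        s = self.synthetic
        kwargs = dict(
            n_subjects_pos=s.n_subjects_pos, n_subjects_neg=s.n_subjects_neg,
            channels=tuple(s.channels), fs=s.fs, duration_s=s.duration_s,
            seed=self.seed,
        )
        if s.null:
            from .synthetic import null_effects

            kwargs["effect"] = null_effects()
        elif s.effect is not None:
            kwargs["effect"] = effects_from_dict(s.effect)
        return SynthConfig(**kwargs)

    def ga_config(self) -> GAConfig:
        return GAConfig(seed=self.seed, **self.ga.model_dump())


def load_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; ``overrides`` (e.g. from CLI
    flags) replace top-level keys before validation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    raw.update({k: v for k, v in (overrides or {}).items() if v is not None})
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate_semantics()
    return cfg


__all__ = ["PipelineConfig", "SynthSection", "GASection", "load_config",
           "ClassEffect"]
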