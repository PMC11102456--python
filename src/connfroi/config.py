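"""Pipeline configuration: defaults, YAML parsing and strict validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .synth.cohort import CohortConfig

__all__ = ["PipelineConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with an exhaustive list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline constants in one place.

    Defaults carry the study constants: 0.5 mm resting FD censoring, 1 mm
    task movement spikes, gamma HRF (2.25 s delay, 1.25 s dispersion),
    a 100-point penalty grid over 1e-5..1e2 and a 10% region fraction.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fd_threshold_mm: float = 0.5
    motion_threshold_mm: float = 1.0
    hrf_delay: float = 2.25
    hrf_dispersion: float = 1.25
    hrf_exponent: float = 2.0
    lambda_count: int = 100
    lambda_lo: float = 1e-5
    lambda_hi: float = 1e2
    fractions: tuple[float, ...] = (0.10,)
    evaluation_run: int = 2
    atlas_q: float = 0.1
    atlas_dilate_radius: float = 2.0
    atlas_shift: tuple[float, float] = (4.0, 0.0)
    inner_mse: str = "fold_mean"
    anova_denominators: str = "error"
    compute_final_models: bool = True
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        problems = _check(self)
        if problems:
            raise ConfigError(problems)

    def with_(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def _check(cfg: PipelineConfig) -> list[str]:
    problems = []
    if cfg.fd_threshold_mm <= 0:
        problems.append("fd_threshold_mm must be positive")
    if cfg.motion_threshold_mm <= 0:
        problems.append("motion_threshold_mm must be positive")
    if cfg.hrf_delay < 0 or cfg.hrf_dispersion <= 0:
        problems.append("hrf_delay must be >= 0 and hrf_dispersion > 0")
    if cfg.lambda_count < 2:
        problems.append("lambda_count must be >= 2")
    if not (0 < cfg.lambda_lo < cfg.lambda_hi):
        problems.append("require 0 < lambda_lo < lambda_hi")
    for f in cfg.fractions:
        if not (0 < f <= 1):
            problems.append(f"fraction {f} outside (0, 1]")
    if cfg.evaluation_run not in (1, 2):
        problems.append("evaluation_run must be 1 or 2")
    if not (0 < cfg.atlas_q <= 1):
        problems.append("atlas_q must be in (0, 1]")
    if cfg.inner_mse not in ("fold_mean", "pooled"):
        problems.append("inner_mse must be 'fold_mean' or 'pooled'")
    if cfg.anova_denominators not in ("error", "mixed"):
        problems.append("anova_denominators must be 'error' or 'mixed'")
    return problems


def validate_config(raw: "str | dict | None") -> PipelineConfig:
    """Build a :class:`PipelineConfig` from YAML text or a mapping.

    Missing keys take the documented defaults; unknown keys and type or
    range violations are all reported together.
    """
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        data: dict = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])

    problems: list[str] = []
    pipe_fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    cohort_fields = {f.name for f in dataclasses.fields(CohortConfig)}

    kwargs: dict = {}
    for key, value in data.items():
        if key == "cohort":
            if not isinstance(value, dict):
                problems.append("cohort must be a mapping")
                continue
            unknown = sorted(set(value) - cohort_fields)
            if unknown:
                problems.append(f"unknown cohort keys: {unknown}")
                continue
            try:
                kwargs["cohort"] = CohortConfig(**value)
            except (TypeError, ValueError) as exc:
                problems.append(f"cohort: {exc}")
        elif key not in pipe_fields:
            problems.append(f"unknown key: {key}")
        elif key in ("fractions", "atlas_shift"):
            try:
                kwargs[key] = tuple(value)
            except TypeError:
                problems.append(f"{key} must be a sequence")
        else:
            kwargs[key] = value

    if problems:
        raise ConfigError(problems)
    # seed propagates to the cohort unless the cohort block pins its own
    if "seed" in data and "cohort" not in data:
        kwargs["cohort"] = CohortConfig(seed=int(data["seed"]))
    elif "seed" in data and "cohort" in kwargs and "seed" not in data.get("cohort", {}):
        kwargs["cohort"] = kwargs["cohort"].with_(seed=int(data["seed"]))
    try:
        return PipelineConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError([str(exc)]) from exc
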