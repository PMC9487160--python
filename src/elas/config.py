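"""Run configuration: a validated YAML document driving the CLI commands.

Unknown keys are rejected before any computation starts, so a typo in a
config file fails fast instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from elas.core import ELASConfig
from elas.learners import LearnerSpec
from elas.synthetic import PRESETS, SimSpec


class ConfigError(ValueError):
    """Run configuration is malformed."""


def _from_mapping(cls, d: dict, context: str):
    if not isinstance(d, dict):
        raise ConfigError(f"{context} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


@dataclass
class CohortSource:
    """Where the cohort comes from: a file pair or a simulation preset."""

    path: str | None = None
    schema: str | None = None
    preset: str | None = None
    horizon: float | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if self.preset is not None and self.preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {self.preset!r}; options: {sorted(PRESETS)}"
            )


@dataclass
class PreprocessOptions:
    variance_threshold: float = 0.01
    n_bins: int = 4


@dataclass
class EvaluateOptions:
    methods: list[str] = field(default_factory=lambda: ["elas", "base_cart"])
    n_repeats: int = 10
    test_fraction: float = 0.2
    threshold: float = 0.5


@dataclass
class RunConfig:
    """Top-level run configuration (one YAML document)."""

    seed: int = 0
    output_dir: str = "elas_output"
    log_level: str = "INFO"
    cohort: CohortSource = field(default_factory=CohortSource)
    simulate: SimSpec | None = None
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    elas: ELASConfig = field(default_factory=ELASConfig)
    evaluate: EvaluateOptions = field(default_factory=EvaluateOptions)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("run config must be a mapping")
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = _from_mapping(CohortSource, d["cohort"], "cohort")
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = _from_mapping(SimSpec, d["simulate"], "simulate")
        if "preprocess" in d:
            d["preprocess"] = _from_mapping(PreprocessOptions, d["preprocess"],
                                            "preprocess")
        if "elas" in d:
            e = d["elas"]
            if not isinstance(e, dict):
                raise ConfigError("elas must be a mapping")
            e = dict(e)
            if "learner" in e:
                lrn = e["learner"]
                if isinstance(lrn, str):
                    e["learner"] = LearnerSpec(lrn)
                elif isinstance(lrn, dict):
                    e["learner"] = _from_mapping(LearnerSpec, lrn, "elas.learner")
                else:
                    raise ConfigError("elas.learner must be a name or mapping")
            d["elas"] = _from_mapping(ELASConfig, e, "elas")
        if "evaluate" in d:
            d["evaluate"] = _from_mapping(EvaluateOptions, d["evaluate"],
                                          "evaluate")
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
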