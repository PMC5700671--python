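"""Run configuration: one structured YAML file drives the whole pipeline.

Exactly one of ``input_dir`` (a directory holding patients/stays/labs/
diagnoses CSVs) or ``simulate`` (a synthetic-generator block) must be
present. CLI flags override scalar fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .models import CLASSICAL_COVARIATES
from .synthetic import SynthConfig, config_from_dict


@dataclass
class RunConfig:
    input_dir: str | None = None
    simulate: SynthConfig | None = None
    out_dir: str = "dysnat_out"
    seed: int = 0
    alpha_family: float = 0.05
    min_duration_days: int = 2
    strict_greater: bool = False
    phewas_comparison: str = "normal"  # comparison group for dysnatremia screens
    classical_covariates: list[str] = field(default_factory=lambda: list(CLASSICAL_COVARIATES))
    charlson_map_path: str | None = None
    dementia_codes_path: str | None = None
    render_plots: bool = False
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_dir or simulate must be set")
        if not 0 < self.alpha_family < 1:
            raise ConfigError(f"alpha_family must be in (0, 1), got {self.alpha_family!r}")
        if self.phewas_comparison not in ("normal", "rest"):
            raise ConfigError("phewas_comparison must be 'normal' or 'rest'")
        if self.simulate is not None and not isinstance(self.simulate, SynthConfig):
            raise ConfigError("simulate must be a SynthConfig or mapping")


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a YAML run configuration; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"run config must be a mapping, got {type(raw).__name__}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    sim = raw.pop("simulate", None)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown run-config fields: {sorted(unknown)}")
    cfg = dict(raw)
    if sim is not None:
        if "seed" not in sim and "seed" in cfg:
            sim = {**sim, "seed": cfg["seed"]}
        cfg["simulate"] = config_from_dict(sim)
    return RunConfig(**cfg)
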