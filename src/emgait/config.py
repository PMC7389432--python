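"""Study-level configuration: all pipeline constants in one place.

Collects the acquisition and processing constants (2 kHz sampling, 20/450 Hz
band-pass, 5 Hz envelope cutoff, 20-sample windows, 175 ms minimum phase,
600 ms event tolerance) together with the MLP hyper-parameters and protocol
knobs, with strict validation and YAML round-tripping for the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .exceptions import ParameterError
from .model import MLPConfig
from .synthdata import CHANNEL_NAMES


@dataclass
class StudyConfig:
    sampling_rate: float = 2000.0
    window_len: int = 20
    channel_order: tuple[str, ...] = CHANNEL_NAMES
    target_leg: str = "left"
    hp_cutoff: float = 20.0
    lp_cutoff: float = 450.0
    env_cutoff: float = 5.0
    fir_order: int = 250
    min_phase_ms: float = 175.0
    tolerance_ms: float = 600.0
    k_folds: int = 10
    mlp: MLPConfig = field(default_factory=MLPConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.window_len < 1:
            raise ParameterError("window_len must be >= 1")
        if self.target_leg not in ("left", "right"):
            raise ParameterError("target_leg must be 'left' or 'right'")
        if len(self.channel_order) != 10:
            raise ParameterError("channel_order must list 10 channels")
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ParameterError("need 0 < hp_cutoff < lp_cutoff")
        if self.min_phase_ms < 0 or self.tolerance_ms <= 0:
            raise ParameterError(
                "min_phase_ms must be >= 0 and tolerance_ms > 0"
            )
        if self.k_folds < 2:
            raise ParameterError("k_folds must be >= 2")
        if isinstance(self.mlp, dict):
            self.mlp = MLPConfig(**self.mlp)


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from YAML, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(
            f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}"
        )
    if "mlp" in raw and isinstance(raw["mlp"], dict):
        mlp_known = {f.name for f in dataclasses.fields(MLPConfig)}
        mlp_unknown = set(raw["mlp"]) - mlp_known
        if mlp_unknown:
            raise ParameterError(
                f"unknown mlp config keys: {sorted(mlp_unknown)}"
            )
    if "channel_order" in raw:
        raw["channel_order"] = tuple(raw["channel_order"])
    return StudyConfig(**raw)


def dump_config(cfg: StudyConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    data["channel_order"] = list(cfg.channel_order)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
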