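"""Run configuration shared by the CLI and the orchestrated pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ValidationError
from .models import DEFAULT_GAMMA
from .signals import (
    DEFAULT_MAX_DELAY_MS,
    DEFAULT_MIN_BEATS,
    DEFAULT_MIN_DELAY_MS,
    DEFAULT_WINDOW_S,
)


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run.

    ``seed`` is mandatory for any stochastic command (simulation).  The
    audit flags select the literal typeset penalty-factor expression and
    the mean-BP footnote variant; both default off.
    """

    gamma: float = DEFAULT_GAMMA
    model: str = "dmkbh"
    calibration_method: str = "fptp"
    window_s: float = DEFAULT_WINDOW_S
    min_beats: int = DEFAULT_MIN_BEATS
    min_delay_ms: float = DEFAULT_MIN_DELAY_MS
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS
    pair_index: int = 0
    literal_eq_form: bool = False
    mbp_footnote_form: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.model not in ("mkbh", "dmkbh"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.calibration_method not in ("optp", "mptp", "fptp"):
            raise ValidationError(f"unknown calibration method {self.calibration_method!r}")
        if not (0 < self.min_delay_ms < self.max_delay_ms):
            raise ValidationError("require 0 < min_delay_ms < max_delay_ms")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValidationError("this command is stochastic: a seed is required")
        return int(self.seed)

    @property
    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header_meta(self) -> dict:
        """Metadata block embedded in every output file of a run."""
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "gamma": self.gamma,
            "model": self.model,
            "calibration_method": self.calibration_method,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)
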