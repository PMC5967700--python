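"""Run configuration: model, control, and sweep parameters with defaults.

Serializable to/from YAML or JSON; unknown keys are rejected so typos fail
loudly.  Every CLI output carries the hash of the effective configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from .dynamics import (DEFAULT_BETA, F_HEALTHY, F_PATHOLOGICAL, GAMMA_GRID,
                       X0_HEALTHY, X0_PATHOLOGICAL)
from .errors import ValidationError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # band targets; alpha_* default to the closed-form (2 pi f)^2 values
    f_p: float = F_PATHOLOGICAL
    f_h: float = F_HEALTHY
    alpha_p: float | None = None
    alpha_h: float | None = None
    gamma_grid: list[float] = field(default_factory=lambda: list(GAMMA_GRID))
    beta: float = DEFAULT_BETA
    x0_p: float = X0_PATHOLOGICAL
    x0_h: float = X0_HEALTHY
    T: float = 20.0
    dt: float = 1e-3
    q: float = 1.0
    r: float = 1.0
    gain_update_interval: float = 0.01
    tol_track: float = 0.05
    cost_mode: str = "l2sq"
    seed: int = 0

    def resolved_alpha_p(self) -> float:
        return self.alpha_p if self.alpha_p is not None \
            else (2.0 * math.pi * self.f_p) ** 2

    def resolved_alpha_h(self) -> float:
        return self.alpha_h if self.alpha_h is not None \
            else (2.0 * math.pi * self.f_h) ** 2

    def validate(self) -> None:
        if self.T < self.dt or self.dt <= 0:
            raise ValidationError("need dt > 0 and T >= dt")
        if self.q <= 0 or self.r <= 0:
            raise ValidationError("q and r must be positive")
        if self.cost_mode not in ("l2sq", "l1"):
            raise ValidationError("cost_mode must be 'l2sq' or 'l1'")
        if self.gain_update_interval < self.dt:
            raise ValidationError("gain_update_interval must be >= dt")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
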