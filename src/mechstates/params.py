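"""Free parameters of the emission and transition model.

All parameters are hand-tuned constants rather than fitted quantities; the
shipped defaults are the values used for inference on rabbit distal colon
recordings (middle column of the parameter table):

======== ========== =========================================================
symbol   default    meaning
======== ========== =========================================================
mu_d     2.5 mm     dilation (d - min_d) separating occluded from distended
sigma_d  0.4 mm     width of the occluded/distended soft threshold
sigma_ddot 0.4 mm/s width of the quiet band for the diameter rate
sigma_pdot 3 mmHg/s width of the quiet band for the pressure rate
gamma    0.5        self-transition probability (smoothing; >1/12 penalises
                    state changes between samples)
dt       0.25 s     sampling interval of the aligned maps (4 Hz)
min_d    None       minimum recorded diameter; ``None`` means "resolve per
                    sensor chain from the data", a float forces a global floor
======== ========== =========================================================

``gamma`` is sampling-rate dependent: decoded at a different ``dt`` it should
be re-tuned by the user; no automatic rescaling is performed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ModelParams", "ParameterError", "DEFAULT_PARAMS"]


class ParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


@dataclass(frozen=True)
class ModelParams:
    sigma_d: float = 0.4
    sigma_ddot: float = 0.4
    sigma_pdot: float = 3.0
    mu_d: float = 2.5
    gamma: float = 0.5
    dt: float = 0.25
    min_d: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_d", "sigma_ddot", "sigma_pdot"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be a positive finite number, got {v!r}")
        if not (math.isfinite(self.mu_d) and self.mu_d >= 0):
            raise ParameterError(f"mu_d must be >= 0, got {self.mu_d!r}")
        if not (0.0 < self.gamma < 1.0):
            raise ParameterError(f"gamma must lie in the open interval (0, 1), got {self.gamma!r}")
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ParameterError(f"dt must be positive, got {self.dt!r}")
        if self.min_d is not None and not (math.isfinite(self.min_d) and self.min_d >= 0):
            raise ParameterError(f"min_d must be >= 0 or None, got {self.min_d!r}")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **kwargs)

    def resolve_min_d(self, d) -> float:
        """Diameter floor for one sensor chain: the override if set, else min(d)."""
        if self.min_d is not None:
            return float(self.min_d)
        import numpy as np

        return float(np.min(d))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        """Read parameters from a flat key-value YAML file; missing keys default."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} must contain a mapping")
        return cls.from_dict(data)


DEFAULT_PARAMS = ModelParams()
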