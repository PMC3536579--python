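"""Run configuration: one record tying together noise, penalties, solver
tolerances, sampler ranges, seeds and selection settings.

Configs round-trip through plain YAML and hash stably, so every output
artifact can embed the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .datagen import NoiseModel
from .fitting import PenaltyConfig
from .model import GeneNetworkModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # noise model
    c1: float = 0.1
    c2: float = 0.2
    assay_sigma: float = 0.1
    # penalty weights by parameter class
    penalty_tight: float = 0.1   # degradation rate and Hill exponents
    penalty_loose: float = 1e-4  # production/translation strengths and K's
    # solver
    rtol: float = 1e-8
    atol: float = 1e-10
    # optimizer
    max_iter: int = 400
    angle_tol: float = 1e-4
    step_tol: float = 1e-10
    # truth sampler log-uniform ranges
    tight_range: tuple = (0.5, 2.0)
    wide_range: tuple = (0.25, 4.0)
    # seeds
    truth_seed: int = 1
    noise_seed: int = 2
    start_seed: int = 3
    selection_seed: int = 4
    # selection
    criterion: str = "param"
    stop_d: float = 0.01
    max_iters: int = 20
    n_initial_starts: int = 20
    n_restarts: int = 10
    allow_duplicates: bool = True

    def __post_init__(self):
        for name in ("c1", "c2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("assay_sigma", "penalty_tight", "penalty_loose",
                     "rtol", "atol", "angle_tol", "step_tol", "stop_d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def noise_model(self) -> NoiseModel:
        return NoiseModel(self.c1, self.c2, self.assay_sigma)

    def penalty_config(self, model: GeneNetworkModel) -> PenaltyConfig:
        return PenaltyConfig.default_for(
            model, tight=self.penalty_tight, loose=self.penalty_loose
        )

    def fit_kwargs(self) -> dict:
        return {
            "max_iter": self.max_iter,
            "angle_tol": self.angle_tol,
            "step_tol": self.step_tol,
            "rtol": self.rtol,
            "atol": self.atol,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tight_range"] = list(d["tight_range"])
        d["wide_range"] = list(d["wide_range"])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("tight_range", "wide_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
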