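"""Run configuration shared by the command-line subcommands.

Defaults follow the model's published operating point (tau = 2857,
I = 3.1, x_c = -2.1, 5 random replicates) and the package's documented
choices everywhere else. A YAML file may override any field; command-line
flags override the file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .epileptor import ModelParams, X0_EZ_DEFAULT, X0_HEALTHY_DEFAULT
from .errors import ValidationError
from .stability import EPS_LOC_DEFAULT, EPS_POS_DEFAULT


@dataclass
class RunConfig:
    # model
    tau: float = 2857.0
    I_ext: float = 3.1
    x_c: float = -2.1
    x0_ez: float = X0_EZ_DEFAULT
    x0_healthy: float = X0_HEALTHY_DEFAULT
    # integration
    rtol: float = 1e-8
    atol: float = 1e-8
    horizon: float | None = None  # None -> 10 * tau
    dt_out: float = 1.0
    method: str = "lsoda"
    # event detection
    theta_on: float = 0.0
    theta_off: float = -1.0
    min_duration: float = 5.0
    # stability thresholds
    eps_pos: float = EPS_POS_DEFAULT
    eps_loc: float = EPS_LOC_DEFAULT
    # lesioning
    strategy: str = "lsa"
    max_lesions: int = 100
    seed: int = 0
    replicates: int = 5

    def model_params(self) -> ModelParams:
        return ModelParams(tau=self.tau, I_ext=self.I_ext, x_c=self.x_c)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **overrides)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.as_dict(), sort_keys=False)
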