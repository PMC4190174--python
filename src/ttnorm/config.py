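"""Pipeline configuration: a single YAML file drives every stage.

All modelling constants are surfaced here as defaults rather than being
hard-coded in the stages: the ng/dL unit factor, the age-3 censoring
boundary, anchor placement, the LM convergence settings (1e-9 relative
tolerance, 4,000 iterations), the 5-fold CV over 3-11 parameters, and the
SD-profile estimator settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .harmonize import DEFAULT_CENSOR_AGE


@dataclass
class PipelineConfig:
    seed: int = 0
    input_csv: str | None = None
    sigma: float | None = 0.15  # constant truth SD; None -> default age profile
    n_per_study: int | None = None  # override every profile's n (small test runs)
    censor_age: float = DEFAULT_CENSOR_AGE
    anchor_count: int | None = None  # None -> 1% of dataset
    anchor_age: float = 0.0
    cv_k: int = 5
    param_counts: tuple[int, ...] = tuple(range(3, 12))
    num_degree: int = 3
    den_degree: int = 3
    xtol: float = 1e-9
    max_iter: int = 4000
    sd_method: str = "kernel"
    sd_bandwidth: float = 5.0
    output_dir: str = "ttnorm_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["param_counts"] = list(self.param_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "param_counts" in d:
            d = {**d, "param_counts": tuple(d["param_counts"])}
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
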