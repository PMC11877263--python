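"""Validated run configuration (YAML-backed) for reproducible experiments."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from .molecules import DEFAULT_FIDELITY_NAMES

__all__ = ["RunConfig", "load_config", "config_hash"]


class SyntheticConfig(BaseModel):
    n_molecules: int = 512
    jitter_sd: float = 0.05
    n_fidelities: int = 4
    difference_scales: list[float] = [25.0, 10.0, 4.0]
    noise_sd: float = 0.5
    unit_costs: list[float] = [1.0, 30.0, 300.0, 3000.0]
    fidelity_names: list[str] = list(DEFAULT_FIDELITY_NAMES)


class DescriptorConfig(BaseModel):
    kind: Literal["unsorted_cm", "sorted_cm", "slatm"] = "sorted_cm"
    max_atoms: int | None = None
    cutoff: float = 4.8
    radial_smear: float = 0.05
    angular_smear: float = 0.05
    radial_step: float = 0.03
    angular_step: float = 0.03


class KernelConfig(BaseModel):
    sigma: float | None = None  # None -> median-distance heuristic
    lam: float = 1e-10


class StructureConfig(BaseModel):
    fb: int | str = 1  # baseline fidelity, index or name
    qc_baseline: int | str = 1
    p: float = 2.0
    n_val: int = 32


class RunConfig(BaseModel):
    """Full experiment configuration: generator, descriptor, kernel, models."""

    seed: int = 0
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    descriptor: DescriptorConfig = Field(default_factory=DescriptorConfig)
    kernel: KernelConfig = Field(default_factory=KernelConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    families: list[Literal["krr", "delta", "mfml", "omfml", "mfdelta"]] = [
        "krr", "delta", "mfml", "omfml", "mfdelta"]
    eta_sweep: list[int] = [1, 2, 3, 4, 5]
    n_runs: int = 10
    n_test: int = 128
    n_eval_grid: list[float] = [1500.0, 15000.0, 150000.0, 1500000.0]

    @model_validator(mode="after")
    def _resolve_fidelities(self) -> "RunConfig":
        names = self.synthetic.fidelity_names[: self.synthetic.n_fidelities]
        for attr in ("fb", "qc_baseline"):
            value = getattr(self.structure, attr)
            if isinstance(value, str):
                if value not in names:
                    raise ValueError(f"structure.{attr}: unknown fidelity {value!r}; known: {names}")
                setattr(self.structure, attr, names.index(value) + 1)
            elif not 1 <= value <= len(names):
                raise ValueError(f"structure.{attr}: index {value} outside 1..{len(names)}")
        if self.n_runs < 1 or self.n_test < 1:
            raise ValueError("n_runs and n_test must be positive")
        if sorted(set(self.eta_sweep)) != self.eta_sweep:
            raise ValueError("eta_sweep must be strictly increasing")
        return self


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
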