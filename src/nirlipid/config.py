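"""Run configuration: one YAML-serializable record of every knob a run
uses, so a pipeline invocation is reproducible from its config + seed."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .regress import RegressionConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Serializes round-trip losslessly to YAML; ``config_hash`` fingerprints
    the resolved values for the run log.
    """

    # instrument grid
    grid_start_nm: float = 760.0
    grid_step_nm: float = 2.2
    grid_bands: int = 512
    # preprocessing
    crop_lo_nm: float = 1000.0
    crop_hi_nm: float = 1400.0
    snv_ddof: int = 1
    spike_z_threshold: float = 6.0
    # synthetic study
    n_per_diet: int = 20
    lobe_height: int = 12
    lobe_width: int = 12
    noise_shot: float = 0.003
    noise_readout: float = 2.0
    spike_rate: float = 2e-4
    dirichlet_concentration: float = 150.0
    # regression
    svr_kernel: str = "rbf"
    svr_C: float = 100.0
    svr_epsilon: float = 0.01
    svr_gamma: float | None = None
    # run
    seed: int = 0

    def regression_config(self) -> RegressionConfig:
        return RegressionConfig(
            kernel=self.svr_kernel,
            C=self.svr_C,
            epsilon=self.svr_epsilon,
            gamma=self.svr_gamma,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
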