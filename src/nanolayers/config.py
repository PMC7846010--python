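"""Pipeline configuration, seed fan-out, and run manifests.

A single user-facing seed deterministically fans out to independent
child seeds for each pipeline stage via ``numpy.random.SeedSequence``
spawning, so stages can be rerun in isolation and still reproduce the
full-pipeline results bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["PipelineConfig", "RunManifest", "stage_seed", "load_config"]

_STAGES = ("simulate", "srrf", "ripley", "carpet", "demo")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {_STAGES}")
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(seed).spawn(len(_STAGES))[idx]
    return int(child.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    Lengths are nm unless the field name says otherwise.
    """

    seed: int = 0
    pixel_size_nm: float = 25.0

    # SRRF
    srrf_ring_radius: float = 0.5
    srrf_magnification: int = 10
    srrf_axes_in_ring: int = 8
    srrf_n_frames: int = 100

    # Ripley
    ripley_dr_nm: float = 25.0
    ripley_rmax_nm: float = 625.0
    ripley_n_simulations: int = 200
    ripley_quantile_low: float = 0.01
    ripley_quantile_high: float = 0.99

    # carpets
    carpet_roi_width_um: float = 10.0
    carpet_roi_height_um: float = 5.0
    carpet_dr_nm: float = 25.0
    carpet_max_lag_nm: float = 1000.0
    carpet_peak_floor: float = 0.05

    # demo-scale simulation conditions
    demo_offset_nm: float = 26.0
    demo_n_carpets: int = 8
    demo_deformation_amplitude_nm: float = 200.0
    demo_deformation_corr_length_nm: float = 1000.0
    demo_emitter_density_per_um: float = 50.0
    demo_psf_sigma_nm: float = 40.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, input hashes, outputs."""

    config: dict[str, Any]
    software_version: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, Any] = field(default_factory=dict)

    def add_input(self, name: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[name] = digest

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
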