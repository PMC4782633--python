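"""Run configuration: the study's model constants, losslessly serializable.

Defaults reproduce the study's reference model constants: E = 5 MPa, nu = 0.32,
rho = 2000 kg/m^3, uniform thickness 2 mm, tip spring 20 kN/m per axis,
tip couple forces 1 N, free-edge pressure 2000 Pa, 14 mm nasal-bone
overlap, first 10 modes.  Config files carry mm/MPa units; conversion to
SI happens when the pipeline builds the model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .geometry import OutlineParams


@dataclass(frozen=True)
class RunConfig:
    # geometry (mm)
    geometry: OutlineParams = field(default_factory=OutlineParams)
    thickness_mm: float = 2.0
    mesh_size_mm: float = 2.0
    # material (MPa / - / kg m^-3)
    E_mpa: float = 5.0
    nu: float = 0.32
    rho: float = 2000.0
    # boundary and load conditions
    tip_condition: str = "spring"           # "free" | "spring"
    spring_k: float = 20e3                  # N/m per axis
    load_case: str = "anteroposterior_couple"
    force_n: float = 1.0
    pressure_pa: float = 2000.0
    include_preload: bool = False
    # modal extraction and classification
    n_modes: int = 10
    tau: float = 0.1                        # in-plane (dash) threshold
    eps: float = 0.02                       # nodal-band threshold
    landmark_radius_mm: float = 3.0
    # synthetic-geometry perturbation (0 => idealized model)
    boundary_amplitude: float = 0.0
    thickness_amplitude: float = 0.0
    n_harmonics: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tip_condition not in ("free", "spring"):
            raise ValueError("tip_condition must be 'free' or 'spring'")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geo = d.pop("geometry", {})
        return cls(geometry=OutlineParams(**geo), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "RunConfig":
        geo_kw = {k: kw.pop(k) for k in list(kw) if k in {f.name for f in fields(OutlineParams)}}
        cfg = replace(self, **kw)
        if geo_kw:
            cfg = replace(cfg, geometry=replace(cfg.geometry, **geo_kw))
        return cfg

    def hash(self) -> str:
        """Short provenance hash of the canonical config JSON."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
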