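"""Run configuration: schema, defaults, YAML round trip.

Defaults encode the reference workflow constants: 0.8 / 0.3 mm global /
local mesh size, Poisson ratio 0.49, subset Young's moduli (calcific
20000, lipid 4, fibrous 400, wall 550 kPa), the CTA HU threshold
classes, the 30% outer-wall enlargement rule, and the bundled local
pressure table (systolic / diastolic per patient).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "StenosisConfig",
    "AnatomyConfig",
    "ImagingConfig",
    "ReconstructionConfig",
    "MeshConfig",
    "MaterialConfig",
    "LoadConfig",
    "PostConfig",
    "RunConfig",
    "load_pressure_table",
]


def load_pressure_table() -> pd.DataFrame:
    """Bundled per-patient local carotid pressures (mmHg)."""
    with resources.files("carotidfem.data").joinpath("local_pressures.csv").open() as f:
        df = pd.read_csv(f)
    df["differential_mmhg"] = df["p_systolic_mmhg"] - df["p_diastolic_mmhg"]
    return df


class StenosisConfig(BaseModel):
    branch: str = "CCA"
    center: float = 12.0
    extent: float = 8.0
    area_reduction: float = 0.5
    angle: float = 0.0
    calcific_fraction: float = 0.25
    lipid_fraction: float = 0.15
    eccentricity: float = 0.8


class AnatomyConfig(BaseModel):
    mode: str = "tube"  # "tube" or "bifurcation"
    stenoses: list[StenosisConfig] = Field(default_factory=lambda: [StenosisConfig()])
    spacing: float = 0.5
    n_theta: int = 72
    noise_amplitude: float = 0.012

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("tube", "bifurcation"):
            raise ValueError("anatomy mode must be 'tube' or 'bifurcation'")
        return v


class ImagingConfig(BaseModel):
    enabled: bool = False
    spacing: float = 0.3


class ReconstructionConfig(BaseModel):
    spacing: float = 0.5
    n_control: int = 16
    narrowing_threshold: float = 0.98
    enlargement: float = 1.3
    fillet_radius: float = 1.5


class MeshConfig(BaseModel):
    global_size: float = 0.8
    local_size: float = 0.3


class MaterialConfig(BaseModel):
    calcific_kpa: float = 20000.0
    lipid_kpa: float = 4.0
    fibrous_kpa: float = 400.0
    wall_kpa: float = 550.0
    poisson: float = 0.49

    def table(self):
        from .fem import MaterialTable

        return MaterialTable(
            young_kpa={
                "calcific": self.calcific_kpa,
                "lipid": self.lipid_kpa,
                "fibrous": self.fibrous_kpa,
                "wall": self.wall_kpa,
            },
            poisson=self.poisson,
        )


class LoadConfig(BaseModel):
    patient: int = 1  # row of the bundled pressure table
    p_systolic_mmhg: float | None = None  # override the table
    p_diastolic_mmhg: float | None = None

    def differential(self) -> float:
        from .postprocess import differential_pressure

        if self.p_systolic_mmhg is not None and self.p_diastolic_mmhg is not None:
            return differential_pressure(self.p_systolic_mmhg, self.p_diastolic_mmhg)
        df = load_pressure_table()
        row = df[df["patient"] == self.patient]
        if row.empty:
            raise ValueError(f"patient {self.patient} not in pressure table")
        return differential_pressure(
            float(row["p_systolic_mmhg"].iloc[0]),
            float(row["p_diastolic_mmhg"].iloc[0]),
        )


class PostConfig(BaseModel):
    volume_fraction: float = 0.99
    angular_window_deg: float = 30.0
    sensitivity_multipliers: list[float] = Field(
        default_factory=lambda: [0.5, 0.8, 0.9, 1.0, 1.1, 1.2, 1.5]
    )
    run_sensitivity: bool = False


class RunConfig(BaseModel):
    seed: int = 1
    outdir: str = "runs/default"
    anatomy: AnatomyConfig = Field(default_factory=AnatomyConfig)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    mesh: MeshConfig = Field(default_factory=MeshConfig)
    materials: MaterialConfig = Field(default_factory=MaterialConfig)
    load: LoadConfig = Field(default_factory=LoadConfig)
    post: PostConfig = Field(default_factory=PostConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
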