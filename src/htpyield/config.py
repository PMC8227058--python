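"""Run configuration: schema-validated YAML for the staged pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .cnn import resolve_arch
from .layout import DesignConfig
from .render import RenderParams
from .selection import SelectionScenario
from .simulate import GeneticParams

STAGES = ("simulate", "render", "extract", "train", "metrics", "genetics", "selection")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignModel(_Strict):
    n_families: int = 86
    n_genitors_sexual: int = 10
    n_genitors_apomictic: int = 10
    n_cultivar_checks: int = 4
    n_reps: int = 3
    blocks_per_rep: int = 11
    n_field_rows: int = 22
    n_field_cols: int = 15
    plot_area_m2: float = 4.5
    numbering: str = "row_major"

    def to_dataclass(self) -> DesignConfig:
        return DesignConfig(**self.model_dump())


class GeneticModel(_Strict):
    mu: float = 2000.0
    Vg: float = 44258.0
    Vb: float = 20000.0
    Ve: float = 100000.0
    rho_row: float = 0.3
    rho_col: float = 0.3
    check_effects: dict[str, float] = {}
    rep_effects: list[float] = []
    leaf_frac_mean: float = 0.55
    leaf_frac_sd: float = 0.05
    dead_frac_mean: float = 0.05
    dead_frac_sd: float = 0.02
    moisture_range: tuple[float, float] = (0.70, 0.78)
    sample_green_weight_range: tuple[float, float] = (300.0, 500.0)

    def to_dataclass(self) -> GeneticParams:
        d = self.model_dump()
        d["rep_effects"] = tuple(d["rep_effects"])
        d["moisture_range"] = tuple(d["moisture_range"])
        d["sample_green_weight_range"] = tuple(d["sample_green_weight_range"])
        return GeneticParams(**d)


class RenderModel(_Strict):
    patch_px: int = 64
    plants_per_plot: int = 10
    canopy_gain: float = 0.25
    cover_max: float = 0.85
    hue_noise_sd: float = 10.0
    texture_noise_sd: float = 0.05
    soil_color: tuple[int, int, int] = (115, 92, 66)
    plant_color: tuple[int, int, int] = (62, 138, 70)
    mosaic_gap_px: int = 8

    def to_dataclass(self) -> RenderParams:
        d = self.model_dump()
        d["soil_color"] = tuple(d["soil_color"])
        d["plant_color"] = tuple(d["plant_color"])
        return RenderParams(**d)


class TrainModel(_Strict):
    arch: str = "macnn"
    input_px: int = 64
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1.0e-8
    epochs: int = 40
    batch_size: int = 64
    early_stop_interval: int = 100
    val_fraction: float = 0.1
    augment: bool = True
    k_folds: int = 10

    @field_validator("arch")
    @classmethod
    def _known_arch(cls, v: str) -> str:
        resolve_arch(v)
        return v


class ScenarioModel(_Strict):
    p: float
    i: float | None = None
    label: str = ""
    n_plots: int | None = None
    n_families: int | None = None

    def to_dataclass(self) -> SelectionScenario:
        return SelectionScenario(**self.model_dump())


class SelectionInputModel(_Strict):
    """Direct genetic-parameter input for a genetics-free selection stage."""

    real_H: float
    real_Vg: float
    htp_H: float
    htp_r: float


class GeneticsModel(_Strict):
    fit_rho: bool = True
    max_iter: int = 100


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "runs/demo"
    trait: str = "TDMY"
    stages: list[str] = list(STAGES)
    design: DesignModel = DesignModel()
    genetic: GeneticModel = GeneticModel()
    render: RenderModel = RenderModel()
    train: TrainModel = TrainModel()
    genetics: GeneticsModel = GeneticsModel()
    scenarios: list[ScenarioModel] = [
        ScenarioModel(p=0.10, label="SI = 10%", n_plots=330, n_families=86),
        ScenarioModel(p=0.05, label="SI = 5%", n_plots=660, n_families=172),
        ScenarioModel(p=0.01, label="SI = 1%", n_plots=3300, n_families=860),
    ]
    selection_input: SelectionInputModel | None = None
    n_bins: int | None = 20  # None -> elbow rule

    @field_validator("trait")
    @classmethod
    def _trait(cls, v: str) -> str:
        if v not in ("TDMY", "LDMY"):
            raise ValueError("trait must be TDMY or LDMY")
        return v

    @field_validator("stages")
    @classmethod
    def _stages(cls, v: list[str]) -> list[str]:
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
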