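"""Run configuration: validated, YAML/JSON-loadable, fully echoed into logs.

Defaults reproduce the bundled Hes1 study: stimulus alpha in [0.01, 2]
(resolution 0.05) switchable at {0, 2, 5, 8, 10, 50, 100, 150, 200} min,
measurements of mRNA and total protein every 10 min over [0, 300], K = 8
designed measurements, acceptability threshold T_A = 2.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["DesignConfig", "ScreeningConfig", "PlantConfig", "RunConfig"]


@dataclass
class DesignConfig:
    admissible_times: list = field(default_factory=lambda: [0, 2, 5, 8, 10, 50, 100, 150, 200])
    input_bounds: list = field(default_factory=lambda: [[0.01, 2.0]])
    input_resolution: list = field(default_factory=lambda: [0.05])
    base_input: list = field(default_factory=lambda: [1.0])
    target_input: list = field(default_factory=lambda: [1.0])
    measurement_species: list | None = None       # None = all model outputs
    sampling_dt: float = 10.0
    K: int = 8
    target_states: list = field(default_factory=lambda: ["m", "P1", "P2"])
    optimize_input: bool = True
    input_grid_max_depth: int = 5
    tree_top_candidates: int = 5
    hampel_window: int = 3
    hampel_n_sigma: float = 3.0


@dataclass
class ScreeningConfig:
    n_lhs: int = 10000
    N_A: int = 2000
    T_A: float = 2.0
    C: int = 12
    screen_max_depth: int = 3
    focused_max_depth: int = 5
    rel_tol: float = 0.10
    abs_tol: float = 5.0
    focused_rounds: int = 5
    cluster_sample: int = 600
    k_max: int = 6


@dataclass
class PlantConfig:
    noise_frac: float = 0.10
    n_replicates: int = 3
    # (output_id, time) pairs for the initial (pre-design) dataset
    initial_points: list = field(default_factory=lambda: [
        ["m", 10.0], ["m", 20.0], ["m", 60.0],
        ["P1+P2", 10.0], ["P1+P2", 20.0], ["P1+P2", 60.0]])
    nominal_unknowns: list | None = None          # None = model registry nominal


@dataclass
class RunConfig:
    model: str = "hes1"
    model_overrides: dict = field(default_factory=dict)
    dataset_path: str | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    plant: PlantConfig = field(default_factory=PlantConfig)
    noise_zeta: list = field(default_factory=lambda: [0.05, 0.10, 0.01])
    dense_grid_points: int = 151
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if isinstance(self.design, dict):
            self.design = DesignConfig(**self.design)
        if isinstance(self.screening, dict):
            self.screening = ScreeningConfig(**self.screening)
        if isinstance(self.plant, dict):
            self.plant = PlantConfig(**self.plant)
        if self.design.K < 0:
            raise ValueError("K must be >= 0")
        if self.screening.T_A <= 0:
            raise ValueError("T_A must be positive")
        if len(self.design.input_bounds) != len(self.design.input_resolution):
            raise ValueError("need one resolution per input dimension")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
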