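"""Pipeline configuration: a flat YAML-serialisable record of every
tunable the stages consume.  CLI flags override config values."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import constants as C
from .allocation import DEFAULT_ELAS


@dataclass
class PipelineConfig:
    seed: int = 0
    scenario: str = "planning"
    base_year: int = C.BASE_YEAR
    horizon_year: int = C.HORIZON_YEAR

    # synthetic landscape
    n_rows: int = 214
    n_cols: int = 218
    n_active_cells: int | None = C.TOTAL_AREA
    n_aml_patches: int = 93
    clump_scale: float = 4.0

    # optional real inputs (override the synthetic stage when set)
    base_map: str | None = None
    factors_dir: str | None = None

    # demand / LP
    use_mls_bounds: bool = False
    reclamation_slack: float = 0.1
    include_x12_in_total: bool = True

    # allocation
    tolerance: float = 0.005
    max_iter: int = 2000
    eta: float = 0.05
    elas_mode: str = "incumbent"
    elas: dict = field(default_factory=lambda: {C.CLASS_NAMES[k]: v for k, v in DEFAULT_ELAS.items()})

    # metrics
    connectivity: int = 8
    connect_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.horizon_year <= self.base_year:
            raise ValueError("years must be increasing")
        if self.scenario not in ("planning", "niche", "esv"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name, v in self.elas.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"ELAS for {name} outside [0, 1]")
        for p in (self.base_map, self.factors_dir):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def elas_by_code(self) -> dict[int, float]:
        return {C.NAME_TO_CODE[name]: float(v) for name, v in self.elas.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
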