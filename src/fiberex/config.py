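"""Run configuration: one YAML document drives every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Every stochastic stage carries its own explicit seed; the config
    round-trips read -> write -> read identically.
    """

    # system
    variant: int = 3
    n_monomers: int = 40
    stacking_distance: float = 1.12
    dipole_charge_scale: float = 1.0
    # particle engine
    n_steps: int = 100_000
    save_stride: int = 2000
    temperature: float = 0.35
    timestep: float = 0.004
    friction: float = 1.0
    equilibration_fraction: float = 1 / 3  # leading fraction excluded from analysis
    # surrogate (per microsecond-equivalent time unit)
    k_bulk_def: float = 0.3
    k_def_bulk: float = 14.0
    k_tip_sol: float = 0.0
    k_def_sol: float = 0.0
    exchange_enabled: bool = False
    t_end: float = 500.0
    t_stride: float = 0.01
    # analysis
    n_clusters: int = 3
    block_size: float = 5.0
    pamm_grid_size: int = 1000
    descriptor_rcut: float = 4.0
    # seeds per stage
    seeds: dict = field(
        default_factory=lambda: {
            "simulate": 1,
            "surrogate": 2,
            "classify": 3,
            "soapcluster": 4,
            "metad": 5,
        }
    )
    # bookkeeping
    out_dir: str = "fiberex_out"
    unit_map: dict = field(
        default_factory=lambda: {"sigma_nm": 0.47, "time_unit": "reduced tau"}
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
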