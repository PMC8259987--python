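"""Simulation configuration: parameter sets, schedules, ablation flags.

A :class:`SimulationConfig` fully determines a run together with its
seed; the same (config, seed) pair reproduces outputs bit for bit.
Configs round-trip through YAML for use from the command line.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import yaml

from .gene_network import GeneParams
from .geometry import DEFAULT_R1, DEFAULT_R2
from .mechanics import MechanicsParams, N_COLS_LR, N_ROWS_AP
from .morphogens import FGFParams, RAParams

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation."""

    schedule: str = "rapid"  # rapid | medium | slow
    t_start: float = 11.0
    t_end: float = 14.0
    seed: int = 0

    ra: RAParams = field(default_factory=RAParams)
    fgf: FGFParams = field(default_factory=FGFParams)
    genes: GeneParams = field(default_factory=GeneParams)
    mech: MechanicsParams = field(default_factory=MechanicsParams)

    r1: float = DEFAULT_R1
    r2: float = DEFAULT_R2
    grid_nx: int = 128
    grid_ny: int = 32
    n_rows: int = N_ROWS_AP
    n_cols: int = N_COLS_LR

    dt: float | None = None  # None: diffusion CFL with safety 0.4
    snapshot_every: float = 0.1  # h
    h_field_every: int = 10  # macro steps between hoxb1a-field refreshes
    mech_interval: float = 4e-3  # h between inter-cell force evaluations

    gene_window: tuple = (11.0, 14.0)  # gene regulation active inside
    sorting_window: tuple = (11.0, 14.0)  # selective sorting inside
    disable_convergent_extension: bool = False
    disable_intracellular_advection: bool = False
    multiplicative_noise: bool = False
    slow_reflection: str = "geometric"  # geometric | pointwise

    burn_in_stage1: float = 1.0  # h
    burn_in_stage2: float = 1.0  # h

    def __post_init__(self):
        for w in (self.gene_window, self.sorting_window):
            if not (self.t_start <= w[0] <= w[1] <= self.t_end):
                raise ValueError("windows must lie inside [t_start, t_end]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    """Load a config from YAML; missing keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    sub = {"ra": RAParams, "fgf": FGFParams, "genes": GeneParams, "mech": MechanicsParams}
    for key, val in raw.items():
        if key in sub:
            kwargs[key] = sub[key](**(val or {}))
        elif key in ("gene_window", "sorting_window"):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return SimulationConfig(**kwargs)
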