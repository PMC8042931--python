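"""Simulation configuration: the named parameters of one run.

Eight of these parameters are the swept experimental factors, each with a
high (H) and a low (L) level; the rest are structural constants of the
model.  Configs round-trip through plain dicts and YAML/JSON files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .effects import MagnitudeMode


@dataclass
class SimulationConfig:
    """Full parameter set for one simulation run."""

    # swept experimental parameters
    te_progeny: int = 1
    te_excision_rate: float = 0.03
    te_death_rate: float = 0.005
    insertion_bias: float = 1.0
    corrected_mutation_rate: float = 0.01
    gene_count: int = 500                 # the NP_BP parameter: genome size
    mutation_effect: float = 0.1
    carrying_capacity: int = 100

    # insertion-effect distribution
    bp: float = 0.20                      # beneficial probability
    p_lethal: float = 0.30
    p_deleterious: float = 0.20
    magnitude_mode: str = "uniform"       # "uniform" | "fixed"

    # genome structure
    gene_length: int = 1000
    te_length: int = 1000
    intergenic_length: Optional[int] = None   # default: 10% of genic bp
    initial_te_count: int = 1

    # run control
    g_max: int = 1000
    seed: int = 0
    step_parents: bool = True             # parents also mutate/transpose
    selection_mode: str = "bernoulli"     # "bernoulli" | "exact"
    dead_te_retains_bp: bool = True
    inactivate_nested_target: bool = False
    record_trajectory: bool = True

    def __post_init__(self):
        if self.carrying_capacity < 0:
            raise ValueError("carrying_capacity must be >= 0")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        MagnitudeMode(self.magnitude_mode)  # validate

    @property
    def mode(self) -> MagnitudeMode:
        return MagnitudeMode(self.magnitude_mode)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    def replace(self, **kw: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)
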