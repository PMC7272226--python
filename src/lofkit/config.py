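"""Run configuration: thresholds, population constants, seeds, paths.

Serialised as plain YAML; a round trip through ``to_yaml``/``from_yaml``
is the identity.  Every numeric threshold used by the pipeline lives
here so that outputs trace to a single place.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .populations import CONSANGUINEOUS_WORLD_FRACTION, DEFAULT_AUTOZYGOSITY


@dataclass
class RunConfig:
    # simulation
    n_genes: int = 1000
    caf_range: tuple[float, float] = (1e-6, 1e-2)
    n_individuals: int = 10_000
    founder_haplotypes: int = 200
    structures: tuple[str, ...] = ("outbred", "bottlenecked", "consanguineous")
    seed: int = 0
    # thresholds
    maf_caf: float = 0.05  # MAF cutoff for CAF estimation
    maf_constraint: float = 0.001  # MAF cutoff for constraint counting
    pli_cutoff: float = 0.9
    alpha: float = 0.05
    # population constants
    autozygosity_a: float = DEFAULT_AUTOZYGOSITY
    consanguineous_world_fraction: float = CONSANGUINEOUS_WORLD_FRACTION
    # flag-simulation rates for the synthetic gene table
    omim_rate: float = 0.18
    two_hit_rate: float = 0.18
    drug_target_rate: float = 0.02

    def __post_init__(self) -> None:
        self.caf_range = tuple(self.caf_range)
        self.structures = tuple(self.structures)
        for name in ("maf_caf", "maf_constraint", "pli_cutoff", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["caf_range"] = list(self.caf_range)
        d["structures"] = list(self.structures)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        try:
            is_file = Path(source).is_file()
        except (OSError, ValueError):
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the serialised configuration."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
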