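"""Population-structure definitions used throughout the package.

Three idealised population structures are modelled:

``outbred``
    Random mating; genotype frequencies follow Hardy-Weinberg
    proportions of the cumulative pLoF allele frequency ``p``.
``bottlenecked``
    A population descended from a limited founder pool (for example
    Finland).  The closed-form genotype frequencies are the same
    Hardy-Weinberg expressions, but evaluated with a population-specific
    ``p``; the distorted allele-frequency spectrum itself is produced
    only by the simulator.
``consanguineous``
    Individuals whose parents are related carry a fraction ``a`` of
    their genome autozygous (identical by descent).  With probability
    ``a`` a locus is IBD, forcing homozygosity of whichever haplotype
    was inherited, so the two-hit frequency is ``(1 - a) p**2 + a p``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

#: Mean autozygous genome fraction among individuals reporting
#: second-cousin-or-closer parents in a large consanguineous cohort
#: (0.05766, conventionally rounded to 5.8%).
DEFAULT_AUTOZYGOSITY = 0.058

#: Estimated fraction of the world population with second-cousin or
#: closer parents.
CONSANGUINEOUS_WORLD_FRACTION = 0.104

#: Inbreeding coefficient expected for the offspring of second cousins
#: (1/64).  See :mod:`lofkit.pedigree` for the path-counting derivation.
SECOND_COUSIN_F = 0.015625

#: Inbreeding-coefficient threshold used to label an individual as
#: consanguineous in cohort metadata.
DEFAULT_INBREEDING_THRESHOLD_F = 0.05


class Structure(str, enum.Enum):
    """Population structure under which genotype frequencies are computed."""

    OUTBRED = "outbred"
    BOTTLENECKED = "bottlenecked"
    CONSANGUINEOUS = "consanguineous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StructureParams:
    """Parameters attached to a population structure.

    Parameters
    ----------
    structure
        One of :class:`Structure` (or its string value).
    autozygosity_a
        Mean autozygous genome fraction ``a``; only used when
        ``structure == Structure.CONSANGUINEOUS``.
    """

    structure: Structure = Structure.OUTBRED
    autozygosity_a: float = DEFAULT_AUTOZYGOSITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", Structure(self.structure))
        if not (0.0 <= self.autozygosity_a < 1.0):
            raise ValueError("autozygosity_a must lie in [0, 1)")
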