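"""Sequential knockout-roadmap classification of genes.

Each gene is assigned the first matching category, in order:

1. ``mendelian_disease`` — a Mendelian disease association is already
   known (curated disease-gene list membership);
2. ``two_hit_reported`` — a two-hit (homozygous or compound
   heterozygous) pLoF genotype has been reported in some cohort;
3. ``likely_haploinsufficient`` — pLI > 0.9, suggesting intolerance of
   heterozygous inactivation;
4. ``plof_not_observed`` — no pLoF variant observed (CAF = 0);
5. ``plof_observed`` — pLoF variants seen but none of the above.

The ordering encodes data availability: disease association trumps
genotype reports, which trump statistical intolerance, which trumps the
raw observation status.
"""

from __future__ import annotations

import enum
import warnings
from typing import Iterable, Optional

import pandas as pd

from .caf import CafEstimate
from .io import GeneRecord


class RoadmapCategory(str, enum.Enum):
    MENDELIAN_DISEASE = "mendelian_disease"
    TWO_HIT_REPORTED = "two_hit_reported"
    LIKELY_HAPLOINSUFFICIENT = "likely_haploinsufficient"
    PLOF_NOT_OBSERVED = "plof_not_observed"
    PLOF_OBSERVED = "plof_observed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_gene(
    record: GeneRecord,
    caf: Optional[CafEstimate],
    pli_cutoff: float = 0.9,
) -> RoadmapCategory:
    """Assign the first matching roadmap category to one gene.

    A missing pLI skips the haploinsufficiency rule (with a warning);
    a missing or censored CAF estimate is treated as CAF = 0.
    """
    if "omim_disease" in record.flags:
        return RoadmapCategory.MENDELIAN_DISEASE
    if "two_hit_reported" in record.flags:
        return RoadmapCategory.TWO_HIT_REPORTED
    if record.pli is None:
        warnings.warn(
            f"{record.gene_id}: pLI missing, haploinsufficiency rule skipped"
        )
    elif record.pli > pli_cutoff:
        return RoadmapCategory.LIKELY_HAPLOINSUFFICIENT
    p = 0.0 if caf is None else caf.p
    if p == 0.0:
        return RoadmapCategory.PLOF_NOT_OBSERVED
    return RoadmapCategory.PLOF_OBSERVED


def summarize_roadmap(
    categories: Iterable[RoadmapCategory],
) -> pd.DataFrame:
    """Counts and fractions per category (all five categories always listed)."""
    cats = list(categories)
    n = len(cats)
    rows = []
    for cat in RoadmapCategory:
        count = sum(1 for c in cats if c is cat)
        rows.append(
            {
                "category": cat.value,
                "count": count,
                "fraction": count / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])
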