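"""Genetic prevalence arithmetic.

Genetic prevalence of a gene: the proportion of individuals at birth
carrying a pathogenic variant in it that will later cause disease.
Estimated as disease incidence (new cases per person-year) x proportion
of cases attributable to the gene x mean age at death in cases, unless
a direct measurement is available, which takes precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional


@dataclass
class PrevalenceInputs:
    incidence: Optional[float] = None  # cases per person-year
    proportion_gene: Optional[float] = None  # fraction of cases from this gene
    mean_age_at_death: Optional[float] = None  # years
    direct_estimate: Optional[float] = None  # overrides the product form

    def __post_init__(self) -> None:
        for name in ("incidence", "proportion_gene", "mean_age_at_death", "direct_estimate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.proportion_gene is not None and self.proportion_gene > 1:
            raise ValueError("proportion_gene must not exceed 1")


@dataclass
class PrevalenceEstimate:
    fraction: float
    one_in_n: str  # e.g. "1 in 49,800"


def estimate_genetic_prevalence(inputs: PrevalenceInputs) -> PrevalenceEstimate:
    """Compute genetic prevalence from the product form or a direct estimate.

    Returns the prevalence as a fraction together with the conventional
    "1 in N" rendering (N rounded to three significant figures).  A
    product exceeding 1 is clipped with a warning.
    """
    if inputs.direct_estimate is not None:
        prev = inputs.direct_estimate
    else:
        components = (inputs.incidence, inputs.proportion_gene, inputs.mean_age_at_death)
        if any(c is None for c in components):
            raise ValueError(
                "need incidence, proportion_gene and mean_age_at_death "
                "(or a direct_estimate)"
            )
        prev = inputs.incidence * inputs.proportion_gene * inputs.mean_age_at_death
    if prev > 1.0:
        warnings.warn(f"prevalence {prev:g} exceeds 1; clipping")
        prev = 1.0
    return PrevalenceEstimate(fraction=prev, one_in_n=_one_in_n(prev))


def _one_in_n(fraction: float) -> str:
    if fraction <= 0:
        return "0 (none expected)"
    n = 1.0 / fraction
    # round to three significant figures for readability
    magnitude = max(0, len(f"{n:.0f}") - 3)
    n_rounded = round(n, -magnitude) if magnitude else round(n)
    return f"1 in {n_rounded:,.0f}"
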