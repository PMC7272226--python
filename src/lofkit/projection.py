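"""Genotype-frequency closed forms and knockout-discovery sample sizes.

Given a gene's cumulative pLoF allele frequency ``p``, in the absence of
natural selection:

* heterozygote frequency = ``2 p (1 - p)`` under every structure;
* two-hit (homozygote + compound heterozygote) frequency ``f``:
  ``p**2`` in outbred and bottlenecked populations (the latter simply
  uses a population-specific ``p``), and ``(1 - a) p**2 + a p`` in
  consanguineous individuals with mean autozygous genome fraction ``a``.

Two sample-size projections follow from ``f``:

* discovery: the smallest cohort in which at least one two-hit
  individual is expected, ``ceil(1/f)`` (or, optionally, the smallest
  cohort in which one is seen with probability >= 1/2);
* lethality inference: the smallest cohort whose complete absence of
  two-hit individuals rejects "the genotype is tolerated" at level
  ``alpha``, i.e. the smallest N with ``(1 - f)**N <= alpha``.

For small ``f`` the two differ by a factor approaching ``-ln(alpha)``
(about 3.0 at ``alpha = 0.05``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd

from .caf import CafEstimate
from .populations import Structure, StructureParams

Count = Union[int, float]  # math.inf marks an unattainable sample size


@dataclass
class KnockoutProjection:
    """Per-gene genotype frequencies and sample-size projections."""

    gene_id: str
    structure: Structure
    p: float
    het_freq: float
    two_hit_freq: float
    n_discovery: Count
    n_lethality: Count
    alpha: float = 0.05


def genotype_frequencies(
    p: float, params: StructureParams = StructureParams()
) -> tuple[float, float]:
    """Heterozygote and two-hit genotype frequencies for allele frequency ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    het = 2.0 * p * (1.0 - p)
    if params.structure is Structure.CONSANGUINEOUS:
        a = params.autozygosity_a
        two_hit = (1.0 - a) * p * p + a * p
    else:
        two_hit = p * p
    return het, two_hit


def discovery_sample_size(two_hit_freq: float, rule: str = "expected") -> Count:
    """Cohort size at which discovery of a two-hit individual is projected.

    ``rule="expected"`` (default): smallest N with expected count
    ``N * f >= 1``, i.e. ``ceil(1/f)``.  ``rule="median"``: smallest N
    with ``P(at least one) >= 1/2``, which is smaller by a factor
    approaching ``ln 2``.  ``f = 0`` is reported as unattainable
    (``math.inf``).
    """
    f = two_hit_freq
    if not (0.0 <= f <= 1.0):
        raise ValueError("two_hit_freq must lie in [0, 1]")
    if f == 0.0:
        return math.inf
    if rule == "expected":
        return math.ceil(1.0 / f)
    if rule == "median":
        if f == 1.0:
            return 1
        return max(1, math.ceil(math.log(0.5) / math.log1p(-f)))
    raise ValueError("rule must be 'expected' or 'median'")


def lethality_sample_size(two_hit_freq: float, alpha: float = 0.05) -> Count:
    """Cohort size at which zero observed two-hit individuals implies lethality.

    Smallest N with ``(1 - f)**N <= alpha``, i.e.
    ``ceil(ln alpha / ln(1 - f))``; one-sided at level ``alpha``.
    """
    f = two_hit_freq
    if not (0.0 <= f <= 1.0):
        raise ValueError("two_hit_freq must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if f == 0.0:
        return math.inf
    if f == 1.0:
        return 1
    return max(1, math.ceil(math.log(alpha) / math.log1p(-f)))


def project_gene(
    caf: CafEstimate,
    params: StructureParams = StructureParams(),
    alpha: float = 0.05,
    discovery_rule: str = "expected",
) -> KnockoutProjection:
    """Assemble frequencies and projections for one gene under one structure."""
    het, two_hit = genotype_frequencies(caf.p, params)
    return KnockoutProjection(
        gene_id=caf.gene_id,
        structure=params.structure,
        p=caf.p,
        het_freq=het,
        two_hit_freq=two_hit,
        n_discovery=discovery_sample_size(two_hit, rule=discovery_rule),
        n_lethality=lethality_sample_size(two_hit, alpha=alpha),
        alpha=alpha,
    )


def projection_frame(projections: Iterable[KnockoutProjection]) -> pd.DataFrame:
    """Tabulate projections (one row per gene x structure)."""
    rows = [
        {
            "gene_id": pr.gene_id,
            "structure": str(pr.structure),
            "p": pr.p,
            "het_freq": pr.het_freq,
            "two_hit_freq": pr.two_hit_freq,
            "n_discovery": pr.n_discovery,
            "n_lethality": pr.n_lethality,
            "alpha": pr.alpha,
        }
        for pr in projections
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "structure",
            "p",
            "het_freq",
            "two_hit_freq",
            "n_discovery",
            "n_lethality",
            "alpha",
        ],
    )
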