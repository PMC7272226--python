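"""Cumulative pLoF allele frequency (CAF) estimation from carrier counts.

Let ``q`` be the proportion of individuals in a cohort carrying no pLoF
allele in a gene.  Under Hardy-Weinberg proportions ``q = (1 - p)**2``
where ``p`` is the cumulative frequency of all pLoF alleles, so

    p = 1 - sqrt(q).

Counting carriers rather than alleles is deliberately conservative: an
individual carrying two different pLoF variants is assumed to carry them
in *cis* and contributes a single pLoF allele, so ``p`` never exceeds
the per-variant allele-frequency sum.  A gene with no observed carriers
is reported as ``p = 0`` and flagged censored, since pLoF alleles may
simply not yet have been sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class CarrierSummary:
    """Per-gene cohort tallies of pLoF carriers.

    ``n_carriers`` counts individuals with at least one pLoF allele;
    ``n_two_hit_observed`` counts individuals whose two haplotypes each
    carry at least one pLoF variant (homozygotes and putative compound
    heterozygotes).
    """

    gene_id: str
    n_individuals: int
    n_carriers: int
    n_two_hit_observed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        if not (0 <= self.n_two_hit_observed <= self.n_carriers <= self.n_individuals):
            raise ValueError(
                "require 0 <= n_two_hit_observed <= n_carriers <= n_individuals"
            )


@dataclass
class CafEstimate:
    """Estimated cumulative pLoF allele frequency for one gene."""

    gene_id: str
    p: float
    q: float
    n_individuals: int
    caf_censored: bool = False


def carrier_summary(
    genotypes: Iterable[tuple[Sequence, Sequence]], gene_id: str
) -> CarrierSummary:
    """Tally carriers from per-individual haplotype states.

    ``genotypes`` yields one ``(haplotype1, haplotype2)`` pair per
    individual, each haplotype a collection of carried pLoF variant
    identifiers.  Any number of distinct variants on an individual's
    haplotypes contributes exactly one carrier (the conservative *cis*
    convention); an individual counts as two-hit when both haplotypes
    are non-empty.
    """
    n = carriers = two_hit = 0
    for hap1, hap2 in genotypes:
        n += 1
        h1, h2 = len(hap1) > 0, len(hap2) > 0
        if h1 or h2:
            carriers += 1
        if h1 and h2:
            two_hit += 1
    if n == 0:
        raise ValueError("cannot summarise an empty cohort")
    return CarrierSummary(gene_id, n, carriers, two_hit)


def estimate_caf(summary: CarrierSummary) -> CafEstimate:
    """Estimate ``p = 1 - sqrt(q)`` from a carrier summary.

    A singleton gene (one carrier among ``n``) yields
    ``p = 1 - sqrt(1 - 1/n)``, which agrees with the allele-counting
    convention ``1/(2n)`` to first order.
    """
    if summary.n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    q = 1.0 - summary.n_carriers / summary.n_individuals
    p = 1.0 - math.sqrt(q)
    return CafEstimate(
        gene_id=summary.gene_id,
        p=p,
        q=q,
        n_individuals=summary.n_individuals,
        caf_censored=summary.n_carriers == 0,
    )


def caf_frame(estimates: Iterable[CafEstimate]) -> pd.DataFrame:
    """Tabulate estimates with columns gene_id, n, n_carriers, q, p, caf_censored."""
    rows = []
    for e in estimates:
        n_carriers = round(e.n_individuals * (1.0 - e.q))
        rows.append(
            {
                "gene_id": e.gene_id,
                "n": e.n_individuals,
                "n_carriers": int(n_carriers),
                "q": e.q,
                "p": e.p,
                "caf_censored": e.caf_censored,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n", "n_carriers", "q", "p", "caf_censored"]
    )
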