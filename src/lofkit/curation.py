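"""Region-restricted variant curation and positional diagnostics.

Automated pLoF filters leave error modes that only show up in where
variants fall along a gene: alignment artefacts piling into repeat
regions, pLoF calls in exons a tissue never expresses, or truncations
past a domain boundary that act as gain-of-function rather than loss.
This module restricts variant sets and expected counts to sub-gene
regions — codon intervals or expression-defined exon sets — and
summarises positional clustering.

Codon intervals are 1-based and inclusive on both ends, so a mask over
codons 1-144 places a variant at codon 144 inside and one at codon 145
outside.  Manual curation verdicts are consumed as data (a per-variant
verdict column), never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constraint import ConstraintResult, constraint_result, region_adjusted_expected
from .io import VariantRecord

#: Default expression level above which an exon counts as expressed.
DEFAULT_EXPRESSION_THRESHOLD = 1.0

#: Curation verdicts that keep a variant as a true LoF call.
PASSING_VERDICTS = frozenset({"pass"})


@dataclass
class RegionMask:
    """A sub-gene region: a codon interval or a set of exons.

    For codon intervals, ``mu_region_sum``/``mu_gene_sum`` carry the
    summed mutation frequencies of all possible pLoF variants in the
    region and the whole transcript, used to rescale expected counts.
    """

    gene_id: str
    kind: str = "codon_interval"  # "codon_interval" | "exon_set"
    codon_start: int = 1
    codon_end: Optional[int] = None
    included_exons: frozenset = frozenset()
    mu_region_sum: Optional[float] = None
    mu_gene_sum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("codon_interval", "exon_set"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if self.kind == "codon_interval":
            if self.codon_end is None or not (1 <= self.codon_start <= self.codon_end):
                raise ValueError("require 1 <= codon_start <= codon_end")
        if self.mu_region_sum is not None and self.mu_gene_sum is not None:
            if not (0 <= self.mu_region_sum <= self.mu_gene_sum):
                raise ValueError("require 0 <= mu_region_sum <= mu_gene_sum")

    def contains(self, variant: VariantRecord) -> Optional[bool]:
        """True/False for membership; None when the needed coordinate is missing."""
        if self.kind == "codon_interval":
            if variant.codon_index is None:
                return None
            return self.codon_start <= variant.codon_index <= self.codon_end
        if variant.exon_id is None:
            return None
        return variant.exon_id in self.included_exons


@dataclass
class MaskPartition:
    inside: list[VariantRecord] = field(default_factory=list)
    outside: list[VariantRecord] = field(default_factory=list)
    unassigned: list[VariantRecord] = field(default_factory=list)


def apply_region_mask(
    variants: Sequence[VariantRecord], mask: RegionMask
) -> MaskPartition:
    """Partition variants by mask membership (counts are conserved).

    Variants missing the coordinate the mask needs are routed to the
    ``unassigned`` bucket rather than silently dropped.
    """
    out = MaskPartition()
    for v in variants:
        member = mask.contains(v)
        if member is None:
            out.unassigned.append(v)
        elif member:
            out.inside.append(v)
        else:
            out.outside.append(v)
    return out


def constitutive_exon_set(
    expressions: pd.DataFrame,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    required_tissues: Optional[Sequence[str]] = None,
) -> frozenset:
    """Exons expressed at or above ``threshold`` in every required tissue.

    ``expressions`` has one row per exon x tissue with columns
    ``exon_id``, ``tissue``, ``expression_value``.  When
    ``required_tissues`` is None, all tissues present in the table are
    required.  An exon missing a required tissue row is excluded.
    """
    if expressions.empty:
        return frozenset()
    tissues = set(required_tissues) if required_tissues else set(expressions["tissue"])
    keep = []
    for exon_id, sub in expressions.groupby("exon_id"):
        sub = sub[sub["tissue"].isin(tissues)]
        if set(sub["tissue"]) != tissues:
            continue
        if (sub["expression_value"] >= threshold).all():
            keep.append(exon_id)
    return frozenset(keep)


def apply_verdicts(
    variants: Sequence[VariantRecord],
    verdicts: Mapping[str, str],
    default: str = "pass",
) -> list[VariantRecord]:
    """Keep variants whose manual-curation verdict passes.

    Verdicts (pass | artefact | annotation_error | not_lof) are keyed by
    ``VariantRecord.variant_id``; variants without a verdict receive
    ``default``.
    """
    return [
        v
        for v in variants
        if verdicts.get(v.variant_id, default) in PASSING_VERDICTS
    ]


def curated_constraint(
    variants_passing: Sequence[VariantRecord],
    mask: RegionMask,
    expected_gene: float,
    alpha: float = 0.05,
) -> ConstraintResult:
    """Region-restricted constraint from curated variants.

    Observed = curated variants falling inside the mask; expected = the
    whole-gene expectation rescaled by the mask's mutation-frequency
    ratio (codon-interval masks with mu sums) or used unchanged when no
    weights are available.  With an identity mask this reduces exactly
    to the whole-gene constraint.
    """
    inside = apply_region_mask(variants_passing, mask).inside
    if mask.mu_region_sum is not None and mask.mu_gene_sum is not None:
        expected = region_adjusted_expected(
            expected_gene, mask.mu_region_sum, mask.mu_gene_sum
        )
    else:
        expected = expected_gene
    region_id = (
        f"{mask.gene_id}:{mask.codon_start}-{mask.codon_end}"
        if mask.kind == "codon_interval"
        else f"{mask.gene_id}:exons"
    )
    return constraint_result(len(inside), expected, region_id, alpha=alpha)


@dataclass
class PositionalDistribution:
    """Histogram of variant codon positions plus a clustering statistic."""

    counts: np.ndarray
    bin_edges: np.ndarray
    max_gap: float  # longest run of empty bins, in codons


def positional_distribution(
    variants: Sequence[VariantRecord] | Iterable[int],
    gene_length: int,
    n_bins: int = 10,
) -> PositionalDistribution:
    """Bin variant codon positions over ``[1, gene_length]``.

    Accepts variant records (their ``codon_index``) or raw codon
    integers.  ``max_gap`` is the longest contiguous stretch of empty
    bins, in codons — a descriptive statistic for positional
    clustering (uniformly scattered variants leave short gaps; variants
    confined to one end leave a gap close to the gene length).
    """
    positions = [
        v.codon_index if isinstance(v, VariantRecord) else int(v) for v in variants
    ]
    positions = [p for p in positions if p is not None]
    edges = np.linspace(0.5, gene_length + 0.5, n_bins + 1)
    counts, _ = np.histogram(positions, bins=edges)
    bin_width = gene_length / n_bins
    longest = run = 0
    for c in counts:
        run = run + 1 if c == 0 else 0
        longest = max(longest, run)
    return PositionalDistribution(
        counts=counts, bin_edges=edges, max_gap=longest * bin_width
    )


def read_region_masks(tsv_path) -> list[RegionMask]:
    """Read codon-interval masks from a TSV.

    Columns: gene_id, kind, codon_start, codon_end, mu_region_sum,
    mu_gene_sum (mu columns optional/NA).
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    masks = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        masks.append(
            RegionMask(
                gene_id=str(d["gene_id"]),
                kind=str(d.get("kind", "codon_interval")),
                codon_start=int(d.get("codon_start", 1)),
                codon_end=int(d["codon_end"]) if not pd.isna(d.get("codon_end")) else None,
                mu_region_sum=None
                if pd.isna(d.get("mu_region_sum"))
                else float(d["mu_region_sum"]),
                mu_gene_sum=None
                if pd.isna(d.get("mu_gene_sum"))
                else float(d["mu_gene_sum"]),
            )
        )
    return masks
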