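"""Published curated-region inputs for neurodegenerative GoF genes.

These entries carry the inputs needed to reproduce the two published
curated-constraint calculations the package is validated against:

* ``MAPT`` restricted to constitutively brain-expressed exons: 12.6
  pLoF variants expected, 0 observed after curation;
* ``PRNP`` restricted to codons 1-144 (truncations at codon >= 145 act
  as gain-of-function and are excluded): 6 curated observed variants
  against a region expectation of 6.06, obtained by rescaling the
  whole-transcript expectation by the region's share of summed pLoF
  mutation frequencies.

The per-codon mutation-frequency weights for PRNP are synthetic
(uniform across the 253-codon reading frame); the whole-transcript
expectation is set so that, under those uniform weights, the rescaled
region expectation matches the published curated pairing.  The real
weights derive from a trinucleotide mutation-rate model that is an
upstream input, not part of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constraint import ConstraintResult, region_adjusted_expected, constraint_result
from .curation import RegionMask


@dataclass(frozen=True)
class CuratedGeneReference:
    gene_id: str
    codon_length: int
    region_start: int
    region_end: int
    observed_curated: int
    expected_transcript: float
    mu_region_sum: float
    mu_gene_sum: float


#: PRNP: single 253-codon coding exon; truncations in codons 1-144 are
#: tolerated LoF, those at codon >= 145 are pathogenic GoF.  Uniform
#: synthetic per-codon weights; transcript expectation consistent with
#: the published region pairing (6 observed / 6.06 expected).
PRNP = CuratedGeneReference(
    gene_id="PRNP",
    codon_length=253,
    region_start=1,
    region_end=144,
    observed_curated=6,
    expected_transcript=6.06 * 253.0 / 144.0,
    mu_region_sum=144.0,
    mu_gene_sum=253.0,
)

#: MAPT restricted to constitutively brain-expressed exons: the
#: restricted transcript's expectation is used directly (no further
#: codon rescaling), with zero curated observations.
MAPT = CuratedGeneReference(
    gene_id="MAPT",
    codon_length=441,
    region_start=1,
    region_end=441,
    observed_curated=0,
    expected_transcript=12.6,
    mu_region_sum=1.0,
    mu_gene_sum=1.0,
)


def curated_region_mask(ref: CuratedGeneReference) -> RegionMask:
    return RegionMask(
        gene_id=ref.gene_id,
        kind="codon_interval",
        codon_start=ref.region_start,
        codon_end=ref.region_end,
        mu_region_sum=ref.mu_region_sum,
        mu_gene_sum=ref.mu_gene_sum,
    )


def curated_region_expected(ref: CuratedGeneReference) -> float:
    """Region expectation from the transcript expectation and mu weights."""
    return region_adjusted_expected(
        ref.expected_transcript, ref.mu_region_sum, ref.mu_gene_sum
    )


def curated_region_constraint(
    ref: CuratedGeneReference, alpha: float = 0.05
) -> ConstraintResult:
    """Curated obs/exp with Poisson upper bound for a reference region."""
    return constraint_result(
        ref.observed_curated,
        curated_region_expected(ref),
        gene_or_region_id=f"{ref.gene_id}:{ref.region_start}-{ref.region_end}",
        alpha=alpha,
    )
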