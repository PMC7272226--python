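"""Synthetic gene catalogs and cohort genotypes.

The generator is the stochastic counterpart of the closed-form genotype
frequencies in :mod:`lofkit.projection`, and exists so that every
downstream stage (I/O, CAF estimation, projections, constraint,
roadmap) can be exercised and validated without any external call set.

What is emulated
----------------
* per-gene true cumulative pLoF allele frequencies spanning several
  orders of magnitude (log-uniform over a configurable range, default
  1e-6 to 1e-2, mirroring the regime of a large exome database);
* variant spectra dominated by ultra-rare alleles: each gene's CAF is
  split over variants most of which sit near the minimum frequency;
* three population structures: Hardy-Weinberg outbred mating; a founder
  bottleneck (every haplotype copied from a small founder pool); and
  consanguinity, where each individual's locus is identical-by-descent
  with probability ``a``.

Variants within a gene are carried independently per haplotype (no
linkage disequilibrium) and two variants on the same haplotype count as
a single pLoF allele, matching the frequency-only treatment and the
conservative *cis* convention of the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .caf import CarrierSummary
from .populations import (
    DEFAULT_AUTOZYGOSITY,
    DEFAULT_INBREEDING_THRESHOLD_F,
    Structure,
)

#: Default per-gene CAF range (log-uniform) for simulated catalogs.
DEFAULT_CAF_RANGE = (1e-6, 1e-2)


@dataclass
class GeneCatalogEntry:
    """Ground truth for one simulated gene.

    ``variant_freqs`` are per-variant allele frequencies summing to
    ``true_caf``; ``variant_codons`` places each variant at a 1-based
    codon of the coding sequence.  ``expected_lof`` is the expected
    pLoF count for a reference cohort under neutrality and ``pli`` an
    upstream haploinsufficiency-intolerance probability; both are
    carried as gene metadata, not derived from the simulation.
    """

    gene_id: str
    true_caf: float
    n_variants: int
    variant_freqs: list[float]
    expected_lof: float
    pli: float
    codon_length: int
    variant_codons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.variant_freqs) - self.true_caf) > 1e-12:
            raise ValueError("variant_freqs must sum to true_caf")
        if any(f <= 0 for f in self.variant_freqs):
            raise ValueError("variant frequencies must be positive")
        if self.true_caf > 1:
            raise ValueError("true_caf must not exceed 1")
        if not self.variant_codons:
            self.variant_codons = [
                1 + (j * self.codon_length) // max(1, self.n_variants)
                for j in range(self.n_variants)
            ]

    def variant_ids(self) -> list[str]:
        return [f"{self.gene_id}:v{j}" for j in range(self.n_variants)]


@dataclass
class CohortSpec:
    """Simulation recipe for one cohort."""

    structure: Structure = Structure.OUTBRED
    n_individuals: int = 10_000
    autozygosity_a: float = DEFAULT_AUTOZYGOSITY
    founder_haplotypes: int = 200
    inbreeding_threshold_F: float = DEFAULT_INBREEDING_THRESHOLD_F
    seed: int = 0

    def __post_init__(self) -> None:
        self.structure = Structure(self.structure)
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        if not (0.0 <= self.autozygosity_a < 1.0):
            raise ValueError("autozygosity_a must lie in [0, 1)")
        if self.structure is Structure.BOTTLENECKED and self.founder_haplotypes < 2:
            raise ValueError("founder_haplotypes must be >= 2 when bottlenecked")


@dataclass
class GeneSim:
    """Simulation output for one gene: sparse haplotype carriage."""

    gene_id: str
    n_individuals: int
    #: variant id -> sorted array of carrier haplotype indices
    #: (haplotypes 2i and 2i+1 belong to individual i)
    carrier_haplotypes: dict[str, np.ndarray]
    summary: CarrierSummary

    def allele_count(self, variant_id: str) -> int:
        return int(self.carrier_haplotypes[variant_id].size)

    def haplotype_sets(self) -> list[tuple[frozenset, frozenset]]:
        """Materialise per-individual haplotype states (small cohorts only)."""
        per_hap: list[set] = [set() for _ in range(2 * self.n_individuals)]
        for vid, haps in self.carrier_haplotypes.items():
            for h in haps:
                per_hap[h].add(vid)
        return [
            (frozenset(per_hap[2 * i]), frozenset(per_hap[2 * i + 1]))
            for i in range(self.n_individuals)
        ]


@dataclass
class SimulatedCohort:
    """A simulated cohort across a gene catalog."""

    spec: CohortSpec
    genes: dict[str, GeneSim]

    @property
    def n_individuals(self) -> int:
        return self.spec.n_individuals

    def summaries(self) -> list[CarrierSummary]:
        return [g.summary for g in self.genes.values()]


def simulate_catalog(
    n_genes: int,
    caf_range: tuple[float, float] = DEFAULT_CAF_RANGE,
    seed: int = 0,
) -> list[GeneCatalogEntry]:
    """Draw a synthetic gene catalog.

    True CAFs are log-uniform over ``caf_range``.  Coding lengths are
    log-normal around ~470 codons (the scale of typical human coding
    sequences) and the number of pLoF variants grows with coding
    length.  Within a gene, at least 80% of variants are "ultra-rare":
    their frequencies fall below ten times the gene's minimum variant
    frequency, with the remaining mass carried by a few higher-frequency
    variants — mimicking a singleton-dominated site-frequency spectrum.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = caf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"invalid caf_range {caf_range!r}: need 0 < lo <= hi < 1")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_genes):
        true_caf = lo if lo == hi else float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        codon_length = int(np.clip(rng.lognormal(math.log(470), 0.6), 30, 30_000))
        n_variants = max(1, round(codon_length / 150))
        freqs = _partition_caf(true_caf, n_variants, rng)
        codons = np.sort(rng.integers(1, codon_length + 1, size=n_variants))
        # expected neutral pLoF count scales with coding length
        expected_lof = float(codon_length / 150 * rng.uniform(0.5, 1.5))
        # bimodal pLI mixture: most genes tolerant, a minority intolerant
        pli = float(rng.beta(0.2, 2.0) if rng.random() < 0.8 else rng.beta(4.0, 0.3))
        entries.append(
            GeneCatalogEntry(
                gene_id=f"GENE{i:05d}",
                true_caf=true_caf,
                n_variants=n_variants,
                variant_freqs=freqs,
                expected_lof=expected_lof,
                pli=pli,
                codon_length=codon_length,
                variant_codons=[int(c) for c in codons],
            )
        )
    return entries


def _partition_caf(total: float, k: int, rng: np.random.Generator) -> list[float]:
    """Split ``total`` into ``k`` positive frequencies, >=80% ultra-rare.

    A bulk of ~85% of variants receives near-minimal weights (uniform in
    [1, 3], so all lie below 10x the minimum weight) while the rest
    receive heavy weights, then all are rescaled to sum to ``total``.
    The sum is renormalised exactly so the invariant holds to 1e-12.
    """
    n_bulk = max(1, math.ceil(0.85 * k))
    weights = np.empty(k)
    weights[:n_bulk] = rng.uniform(1.0, 3.0, size=n_bulk)
    if k > n_bulk:
        weights[n_bulk:] = rng.uniform(30.0, 300.0, size=k - n_bulk)
    freqs = weights / weights.sum() * total
    freqs[-1] = total - freqs[:-1].sum()  # exact renormalisation
    return [float(f) for f in freqs]


def simulate_cohort(catalog: list[GeneCatalogEntry], spec: CohortSpec) -> SimulatedCohort:
    """Simulate per-haplotype variant carriage for every gene in ``catalog``.

    * outbred: every haplotype carries each variant independently with
      its allele frequency;
    * bottlenecked: ``founder_haplotypes`` founder haplotypes are drawn
      as above, then each cohort haplotype copies a founder chosen
      uniformly with replacement;
    * consanguineous: per individual and gene, with probability
      ``autozygosity_a`` the second haplotype is an identical-by-descent
      copy of the first.

    Deterministic for a given catalog and ``spec.seed``.
    """
    genes: dict[str, GeneSim] = {}
    seeds = np.random.SeedSequence(spec.seed).spawn(len(catalog))
    for entry, child_seed in zip(catalog, seeds):
        rng = np.random.default_rng(child_seed)
        genes[entry.gene_id] = _simulate_gene(entry, spec, rng)
    return SimulatedCohort(spec=spec, genes=genes)


def _simulate_gene(
    entry: GeneCatalogEntry, spec: CohortSpec, rng: np.random.Generator
) -> GeneSim:
    n = spec.n_individuals
    n_hap = 2 * n
    vids = entry.variant_ids()
    carrier_haps: dict[str, np.ndarray] = {}
    any_carry = np.zeros(n_hap, dtype=bool)

    if spec.structure is Structure.BOTTLENECKED:
        founder_of = rng.integers(0, spec.founder_haplotypes, size=n_hap)
    elif spec.structure is Structure.CONSANGUINEOUS:
        ibd = rng.random(n) < spec.autozygosity_a

    for vid, f in zip(vids, entry.variant_freqs):
        if spec.structure is Structure.BOTTLENECKED:
            founder_has = rng.random(spec.founder_haplotypes) < f
            carry = founder_has[founder_of]
        else:
            carry = rng.random(n_hap) < f
            if spec.structure is Structure.CONSANGUINEOUS:
                pairs = carry.reshape(n, 2)
                pairs[ibd, 1] = pairs[ibd, 0]
        carrier_haps[vid] = np.flatnonzero(carry)
        any_carry |= carry

    pairs = any_carry.reshape(n, 2)
    h1, h2 = pairs[:, 0], pairs[:, 1]
    summary = CarrierSummary(
        gene_id=entry.gene_id,
        n_individuals=n,
        n_carriers=int(np.count_nonzero(h1 | h2)),
        n_two_hit_observed=int(np.count_nonzero(h1 & h2)),
    )
    return GeneSim(
        gene_id=entry.gene_id,
        n_individuals=n,
        carrier_haplotypes=carrier_haps,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# serialisation

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lofkit-synthetic
##contig=<ID=1>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">
##INFO=<ID=LOF_FLAG,Number=1,Type=String,Description="LoF confidence flag (HC|LC)">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class (nonsense|splice|frameshift)">
##INFO=<ID=CODON,Number=1,Type=Integer,Description="1-based affected codon index">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_CSQ_CYCLE = ("nonsense", "splice", "frameshift")


def write_cohort(
    cohort: SimulatedCohort,
    catalog: list[GeneCatalogEntry],
    out_prefix: str,
) -> tuple[str, str]:
    """Write a sites VCF and a carrier-summary TSV; returns both paths.

    The VCF carries one record per simulated variant (invented
    coordinates on contig 1, cycling consequence classes, all flagged
    high-confidence) with cohort allele counts in INFO.  Variants with
    cohort allele count 0 are omitted, as in a real call set.
    """
    vcf_path = f"{out_prefix}.sites.vcf"
    tsv_path = f"{out_prefix}.carriers.tsv"
    an = 2 * cohort.n_individuals
    pos = 0
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for entry in catalog:
            sim = cohort.genes[entry.gene_id]
            for j, vid in enumerate(entry.variant_ids()):
                pos += 100
                ac = sim.allele_count(vid)
                if ac == 0:
                    continue
                info = (
                    f"GENE={entry.gene_id};AC={ac};AN={an};LOF_FLAG=HC;"
                    f"CSQ_CLASS={_CSQ_CYCLE[j % 3]};CODON={entry.variant_codons[j]}"
                )
                fh.write(f"1\t{pos}\t{vid}\tA\tT\t.\tPASS\t{info}\n")
    summaries = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "n_individuals": s.n_individuals,
                "n_carriers": s.n_carriers,
                "n_two_hit": s.n_two_hit_observed,
            }
            for s in cohort.summaries()
        ],
        columns=["gene_id", "n_individuals", "n_carriers", "n_two_hit"],
    )
    summaries.to_csv(tsv_path, sep="\t", index=False)
    return vcf_path, tsv_path


def catalog_gene_table(
    catalog: list[GeneCatalogEntry],
    seed: int = 0,
    omim_rate: float = 0.18,
    two_hit_rate: float = 0.18,
    drug_target_rate: float = 0.02,
) -> pd.DataFrame:
    """Derive a gene-metadata table with synthetic list-membership flags.

    Flag rates default to the approximate genome-wide fractions of
    genes with a known Mendelian disease association (~18%) or a
    reported two-hit genotype (~18%); flags are drawn independently.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for e in catalog:
        rows.append(
            {
                "gene_id": e.gene_id,
                "symbol": e.gene_id,
                "expected_lof": e.expected_lof,
                "pli": e.pli,
                "coding_codons": e.codon_length,
                "omim_disease": int(rng.random() < omim_rate),
                "two_hit_reported": int(rng.random() < two_hit_rate),
                "drug_target": int(rng.random() < drug_target_rate),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "expected_lof",
            "pli",
            "coding_codons",
            "omim_disease",
            "two_hit_reported",
            "drug_target",
        ],
    )


def single_gene_catalog(
    true_caf: float,
    n_variants: int = 5,
    gene_id: str = "GENE00000",
    codon_length: int = 500,
    seed: int = 0,
) -> list[GeneCatalogEntry]:
    """Convenience catalog with one gene of known CAF (for validation runs)."""
    if true_caf == 0.0:
        # represent a zero-CAF gene as a single never-carried variant
        return [
            GeneCatalogEntry(
                gene_id=gene_id,
                true_caf=0.0,
                n_variants=0,
                variant_freqs=[],
                expected_lof=1.0,
                pli=0.5,
                codon_length=codon_length,
            )
        ]
    rng = np.random.default_rng(seed)
    freqs = _partition_caf(true_caf, n_variants, rng)
    return [
        GeneCatalogEntry(
            gene_id=gene_id,
            true_caf=true_caf,
            n_variants=n_variants,
            variant_freqs=freqs,
            expected_lof=1.0,
            pli=0.5,
            codon_length=codon_length,
        )
    ]
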