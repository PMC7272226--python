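"""Readers, writers and filters for annotated pLoF variants and gene tables.

VCF input is a 4.2 sites file with the INFO keys ``GENE``, ``AC``,
``AN``, ``LOF_FLAG`` (HC|LC), ``CSQ_CLASS`` and ``CODON``; gene
metadata is a TSV with 0/1 flag columns.  Canonical-transcript
resolution is assumed done upstream: each variant maps to a single
gene identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

#: Gene-table flag columns recognised for roadmap / comparison rules.
KNOWN_FLAGS = ("omim_disease", "two_hit_reported", "drug_target", "reference_set")

_MANDATORY_GENE_COLUMNS = ("gene_id", "expected_lof", "pli", "coding_codons")


@dataclass
class VariantRecord:
    """One annotated pLoF variant (one row per gene x alt allele)."""

    gene_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    csq_class: str = "other"
    lof_flag: Optional[str] = None  # "HC" | "LC" | None
    allele_count: int = 0
    allele_number: int = 0
    codon_index: Optional[int] = None
    exon_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValueError("require 0 <= allele_count <= allele_number")

    @property
    def maf(self) -> float:
        """Minor allele frequency, min(AC/AN, 1 - AC/AN)."""
        if self.allele_number == 0:
            return 0.0
        af = self.allele_count / self.allele_number
        return min(af, 1.0 - af)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GeneRecord:
    """Per-gene metadata consumed (not computed) by the analysis."""

    gene_id: str
    symbol: str
    expected_lof: float
    pli: Optional[float]  # None when unavailable
    coding_codons: int
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError("pli must lie in [0, 1]")
        if self.expected_lof < 0:
            raise ValueError("expected_lof must be non-negative")


def read_variants(vcf_path: str | Path) -> list[VariantRecord]:
    """Read pLoF variant records from a sites VCF.

    Multi-allelic sites are split into one record per alternate allele
    (AC is per-allele, Number=A); missing optional INFO keys become
    ``None``.
    """
    records: list[VariantRecord] = []
    vcf = VCF(str(vcf_path))
    try:
        for var in vcf:
            info = dict(var.INFO)
            ac = info.get("AC", 0)
            acs = list(ac) if isinstance(ac, (tuple, list)) else [ac]
            an = int(info.get("AN", 0))
            codon = info.get("CODON")
            for alt, alt_ac in zip(var.ALT, acs):
                records.append(
                    VariantRecord(
                        gene_id=str(info.get("GENE", "")),
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        csq_class=str(info.get("CSQ_CLASS", "other")),
                        lof_flag=info.get("LOF_FLAG"),
                        allele_count=int(alt_ac),
                        allele_number=an,
                        codon_index=int(codon) if codon is not None else None,
                        exon_id=info.get("EXON"),
                    )
                )
    finally:
        vcf.close()
    return records


def filter_lof(
    variants: Sequence[VariantRecord],
    maf_max: float = 0.05,
    require_flag: str = "HC",
) -> list[VariantRecord]:
    """Keep variants with the required LoF flag and MAF strictly below ``maf_max``.

    Both thresholds follow the strict-inequality convention; order is
    preserved and the operation is idempotent.
    """
    if not (0.0 < maf_max <= 1.0):
        raise ValueError("maf_max must lie in (0, 1]")
    return [
        v for v in variants if v.lof_flag == require_flag and v.maf < maf_max
    ]


def read_gene_table(tsv_path: str | Path) -> list[GeneRecord]:
    """Read a gene metadata TSV into typed records.

    Mandatory columns: gene_id, expected_lof, pli, coding_codons (a
    ``symbol`` column is optional and defaults to gene_id).  Flag
    columns among ``KNOWN_FLAGS`` populate ``GeneRecord.flags``;
    unknown 0/1 columns are ignored with a warning.  A pLI of NA marks
    the value missing, excluding the gene from pLI-based rules.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    missing = [c for c in _MANDATORY_GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing mandatory column(s): {', '.join(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicated gene_id(s): {dupes}")
    known = set(_MANDATORY_GENE_COLUMNS) | {"symbol"} | set(KNOWN_FLAGS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown gene-table column(s): {unknown}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pli = d["pli"]
        flags = frozenset(f for f in KNOWN_FLAGS if f in d and int(d[f] or 0) == 1)
        records.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                symbol=str(d.get("symbol", d["gene_id"])),
                expected_lof=float(d["expected_lof"]),
                pli=None if pd.isna(pli) else float(pli),
                coding_codons=int(d["coding_codons"]),
                flags=flags,
            )
        )
    return records


def read_carrier_summaries(tsv_path: str | Path):
    """Read a carrier-summary TSV (written by the simulator) into records."""
    from .caf import CarrierSummary

    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return [
        CarrierSummary(
            gene_id=str(r.gene_id),
            n_individuals=int(r.n_individuals),
            n_carriers=int(r.n_carriers),
            n_two_hit_observed=int(r.n_two_hit),
        )
        for r in df.itertuples(index=False)
    ]
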