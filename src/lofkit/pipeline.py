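"""End-to-end pipeline on simulated data.

Stages: simulate catalog and cohorts -> write/read VCF + carrier TSVs ->
estimate CAF -> project knockout prospects -> classify the roadmap ->
constraint + gene-set comparison.  Every stage writes a TSV whose
header comments record the package version, seed and configuration
hash, and the whole run is byte-for-byte deterministic for a fixed
configuration.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .caf import estimate_caf
from .config import RunConfig
from .io import read_carrier_summaries, read_gene_table, read_variants
from .models import ConstraintModel, KnockoutProspectsModel
from .roadmap import classify_gene, summarize_roadmap
from .synthetic import (
    CohortSpec,
    catalog_gene_table,
    simulate_catalog,
    simulate_cohort,
    write_cohort,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# lofkit {__version__}\n"
        f"# seed={config.seed} config={config.digest()}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and return the output directory.

    Writes, per structure: ``cohort_<structure>.sites.vcf``,
    ``cohort_<structure>.carriers.tsv``, ``caf_<structure>.tsv``; plus
    ``projections.tsv``, ``roadmap.tsv``, ``roadmap_summary.tsv``,
    ``constraint.tsv``, ``comparison.tsv``, ``genes.tsv`` and the
    resolved ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        catalog = simulate_catalog(config.n_genes, config.caf_range, seed=config.seed) \
            if config.n_genes > 0 else []
        gene_table = catalog_gene_table(
            catalog,
            seed=config.seed + 1,
            omim_rate=config.omim_rate,
            two_hit_rate=config.two_hit_rate,
            drug_target_rate=config.drug_target_rate,
        )
        _write_tsv(gene_table, out / "genes.tsv", config)
        cohorts = {}
        for k, structure in enumerate(config.structures):
            spec = CohortSpec(
                structure=structure,
                n_individuals=config.n_individuals,
                autozygosity_a=config.autozygosity_a,
                founder_haplotypes=config.founder_haplotypes,
                seed=config.seed + 100 + k,
            )
            cohort = simulate_cohort(catalog, spec)
            write_cohort(cohort, catalog, str(out / f"cohort_{structure}"))
            cohorts[structure] = cohort
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc) from exc

    stage = "caf"
    try:
        estimates = {}
        for structure in config.structures:
            summaries = read_carrier_summaries(
                out / f"cohort_{structure}.carriers.tsv"
            )
            ests = [estimate_caf(s) for s in summaries]
            estimates[structure] = {e.gene_id: e for e in ests}
            from .caf import caf_frame

            _write_tsv(caf_frame(ests), out / f"caf_{structure}.tsv", config)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "project"
    try:
        frames = []
        for structure in config.structures:
            summaries = read_carrier_summaries(
                out / f"cohort_{structure}.carriers.tsv"
            )
            model = KnockoutProspectsModel(
                summaries,
                structures=[structure],
                autozygosity_a=config.autozygosity_a,
                alpha=config.alpha,
            )
            frames.append(model.fit().frame)
        projections = (
            pd.concat(frames, ignore_index=True) if frames else
            KnockoutProspectsModel([], structures=[]).fit().frame
        )
        _write_tsv(projections, out / "projections.tsv", config)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "roadmap"
    try:
        gene_records = read_gene_table(out / "genes.tsv")
        base_structure = config.structures[0] if config.structures else "outbred"
        cats = []
        rows = []
        for rec in gene_records:
            caf_est = estimates.get(base_structure, {}).get(rec.gene_id)
            cat = classify_gene(rec, caf_est, pli_cutoff=config.pli_cutoff)
            cats.append(cat)
            rows.append({"gene_id": rec.gene_id, "category": cat.value})
        _write_tsv(
            pd.DataFrame(rows, columns=["gene_id", "category"]),
            out / "roadmap.tsv",
            config,
        )
        _write_tsv(summarize_roadmap(cats), out / "roadmap_summary.tsv", config)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "constraint"
    try:
        base_structure = config.structures[0] if config.structures else "outbred"
        observed_by_gene: dict[str, int] = {}
        if config.structures:
            variants = read_variants(out / f"cohort_{base_structure}.sites.vcf")
            from .io import filter_lof

            for v in filter_lof(variants, maf_max=config.maf_constraint):
                observed_by_gene[v.gene_id] = observed_by_gene.get(v.gene_id, 0) + 1
        gdf = gene_table
        observed = [observed_by_gene.get(g, 0) for g in gdf["gene_id"]]
        results = None
        if len(gdf):
            model = ConstraintModel(observed, gdf["expected_lof"], ids=gdf["gene_id"])
            results = model.fit(alpha=config.alpha)
            _write_tsv(results.frame, out / "constraint.tsv", config)
        else:
            _write_tsv(
                pd.DataFrame(
                    columns=["gene_id", "observed", "expected", "oe", "oe_upper", "undefined"]
                ),
                out / "constraint.tsv",
                config,
            )
        comparison_rows = []
        if results is not None and len(gdf) >= 2 and gdf["drug_target"].sum() >= 1:
            cmp = results.compare_sets(
                gdf["drug_target"].astype(bool).to_numpy(),
                label_a="drug_targets",
                label_b="all",
            )
            comparison_rows.append(
                {
                    "set_a": cmp.label_a,
                    "set_b": cmp.label_b,
                    "n_a": cmp.n_a,
                    "n_b": cmp.n_b,
                    "mean_a": cmp.mean_a,
                    "mean_b": cmp.mean_b,
                    "ks_D": cmp.ks_d,
                    "ks_p": cmp.ks_p,
                }
            )
        _write_tsv(
            pd.DataFrame(
                comparison_rows,
                columns=[
                    "set_a", "set_b", "n_a", "n_b", "mean_a", "mean_b", "ks_D", "ks_p",
                ],
            ),
            out / "comparison.tsv",
            config,
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return out
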