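"""Model/Results front-ends over the functional core.

Two model classes give the package a familiar fit-then-inspect surface:

* :class:`KnockoutProspectsModel` — built from per-gene carrier
  summaries; ``fit()`` estimates each gene's cumulative pLoF allele
  frequency and projects heterozygote/two-hit genotype frequencies and
  discovery/lethality sample sizes under the requested population
  structures.
* :class:`ConstraintModel` — built from per-gene observed and expected
  pLoF counts; ``fit()`` returns obs/exp ratios with exact Poisson
  upper bounds and supports gene-set comparisons.

Both accept tidy DataFrames via ``from_dataframe`` and return results
objects with a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constraint as cstats
from .caf import CafEstimate, CarrierSummary, caf_frame, estimate_caf
from .populations import DEFAULT_AUTOZYGOSITY, Structure, StructureParams
from .projection import project_gene, projection_frame


class KnockoutProspectsModel:
    """Knockout-discovery prospects for a set of genes.

    Parameters
    ----------
    summaries
        Per-gene :class:`~lofkit.caf.CarrierSummary` records.
    structures
        Population structures to project under (default: all three).
    autozygosity_a
        Mean autozygous genome fraction for the consanguineous
        projection (default 0.058).
    alpha
        One-sided level for the lethality-inference sample size.
    """

    def __init__(
        self,
        summaries: Sequence[CarrierSummary],
        structures: Sequence[Structure] = tuple(Structure),
        autozygosity_a: float = DEFAULT_AUTOZYGOSITY,
        alpha: float = 0.05,
        discovery_rule: str = "expected",
    ) -> None:
        self.summaries = list(summaries)
        self.structures = [Structure(s) for s in structures]
        self.autozygosity_a = autozygosity_a
        self.alpha = alpha
        self.discovery_rule = discovery_rule

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "KnockoutProspectsModel":
        """Build from a frame with columns gene_id, n_individuals, n_carriers
        and optionally n_two_hit."""
        summaries = [
            CarrierSummary(
                gene_id=str(r.gene_id),
                n_individuals=int(r.n_individuals),
                n_carriers=int(r.n_carriers),
                n_two_hit_observed=int(getattr(r, "n_two_hit", 0)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(summaries, **kwargs)

    def fit(self) -> "KnockoutProspectsResults":
        estimates = [estimate_caf(s) for s in self.summaries]
        projections = []
        for structure in self.structures:
            params = StructureParams(structure, self.autozygosity_a)
            for est in estimates:
                projections.append(
                    project_gene(
                        est,
                        params,
                        alpha=self.alpha,
                        discovery_rule=self.discovery_rule,
                    )
                )
        return KnockoutProspectsResults(self, estimates, projections)


class KnockoutProspectsResults:
    """Fitted CAF estimates and knockout projections."""

    def __init__(self, model, estimates: list[CafEstimate], projections) -> None:
        self.model = model
        self.estimates = estimates
        self.projections = projections
        self.caf = caf_frame(estimates)
        self.frame = projection_frame(projections)

    def median_two_hit_freq(self, structure: Structure | str) -> float:
        sub = self.frame[self.frame["structure"] == str(Structure(structure))]
        return float(sub["two_hit_freq"].median())

    def summary(self) -> str:
        lines = [
            "Knockout prospects",
            "==================",
            f"genes: {len(self.estimates)}   structures: "
            + ", ".join(str(s) for s in self.model.structures),
            f"autozygosity a = {self.model.autozygosity_a:g}   "
            f"alpha = {self.model.alpha:g}",
            "",
        ]
        censored = sum(e.caf_censored for e in self.estimates)
        lines.append(
            f"genes with >=1 pLoF carrier: {len(self.estimates) - censored} "
            f"({(len(self.estimates) - censored) / max(1, len(self.estimates)):.1%})"
        )
        for s in self.model.structures:
            sub = self.frame[self.frame["structure"] == str(s)]
            med = sub["two_hit_freq"].median()
            finite = sub["n_discovery"][np.isfinite(sub["n_discovery"])]
            med_n = finite.median() if len(finite) else float("inf")
            lines.append(
                f"{s!s:>15}: median two-hit freq {med:.3g}; "
                f"median discovery N {med_n:,.0f}"
            )
        return "\n".join(lines)

    def plot_histograms(self, structure: Structure | str = Structure.OUTBRED, ax=None):
        """Histogram of het and two-hit frequencies (log10 scale), one structure."""
        import matplotlib.pyplot as plt

        sub = self.frame[self.frame["structure"] == str(Structure(structure))]
        if ax is None:
            _, ax = plt.subplots()
        for col, color in (("het_freq", "tab:orange"), ("two_hit_freq", "tab:purple")):
            vals = sub[col][sub[col] > 0]
            ax.hist(np.log10(vals), bins=40, alpha=0.6, label=col, color=color)
        ax.set_xlabel("log10 genotype frequency")
        ax.set_ylabel("genes")
        ax.legend()
        return ax


class ConstraintModel:
    """Observed/expected pLoF constraint for a set of genes or regions."""

    def __init__(
        self,
        observed: Sequence[int],
        expected: Sequence[float],
        ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.observed = np.asarray(observed, dtype=int)
        self.expected = np.asarray(expected, dtype=float)
        if self.observed.shape != self.expected.shape:
            raise ValueError("observed and expected must have equal length")
        self.ids = (
            [str(i) for i in ids]
            if ids is not None
            else [f"g{i}" for i in range(self.observed.size)]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConstraintModel":
        """Build from a frame with columns gene_id, observed, expected."""
        return cls(df["observed"], df["expected"], ids=df["gene_id"])

    def fit(self, alpha: float = 0.05) -> "ConstraintResults":
        results = [
            cstats.constraint_result(o, e, gid, alpha=alpha)
            for o, e, gid in zip(self.observed, self.expected, self.ids)
        ]
        return ConstraintResults(self, results, alpha)


class ConstraintResults:
    """Per-gene obs/exp ratios with one-sided Poisson upper bounds."""

    def __init__(self, model: ConstraintModel, results, alpha: float) -> None:
        self.model = model
        self.results = results
        self.alpha = alpha
        self.frame = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_or_region_id,
                    "observed": r.observed,
                    "expected": r.expected,
                    "oe": r.oe,
                    "oe_upper": r.oe_upper,
                    "undefined": r.undefined,
                }
                for r in results
            ],
            columns=["gene_id", "observed", "expected", "oe", "oe_upper", "undefined"],
        )

    @property
    def oe(self) -> np.ndarray:
        return self.frame["oe"].to_numpy()

    @property
    def oe_upper(self) -> np.ndarray:
        return self.frame["oe_upper"].to_numpy()

    def compare_sets(
        self,
        mask_a: Sequence[bool],
        mask_b: Optional[Sequence[bool]] = None,
        label_a: str = "set A",
        label_b: str = "all genes",
    ) -> cstats.GeneSetComparison:
        """KS comparison of obs/exp between two index masks.

        ``mask_b`` defaults to the complement-inclusive full set, the
        usual "set versus all genes" contrast of forest plots.
        """
        oe = self.oe
        a = oe[np.asarray(mask_a, dtype=bool)]
        b = oe if mask_b is None else oe[np.asarray(mask_b, dtype=bool)]
        valid_a, valid_b = a[~np.isnan(a)], b[~np.isnan(b)]
        return cstats.compare_gene_sets(valid_a, valid_b, label_a, label_b)

    def summary(self) -> str:
        defined = self.frame[~self.frame["undefined"]]
        lines = [
            "pLoF constraint (obs/exp)",
            "=========================",
            f"genes/regions: {len(self.frame)}   alpha = {self.alpha:g} (one-sided)",
            f"mean oe: {defined['oe'].mean():.3f}   median oe: {defined['oe'].median():.3f}",
        ]
        if len(defined) <= 12:
            lines.append("")
            lines.append(
                defined.to_string(
                    index=False,
                    formatters={"oe": "{:.3f}".format, "oe_upper": "{:.3f}".format},
                )
            )
        return "\n".join(lines)
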