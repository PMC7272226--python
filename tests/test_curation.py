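"""Region masks, constitutive exons, curated constraint, positional stats."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lofkit.constraint import oe_upper_bound
from lofkit.curation import (
    RegionMask,
    apply_region_mask,
    apply_verdicts,
    constitutive_exon_set,
    curated_constraint,
    positional_distribution,
)
from lofkit.reference import MAPT, PRNP, curated_region_constraint


class TestRegionMask:
    def test_codon_interval_boundaries(self, variant_factory):
        mask = RegionMask("G", codon_start=1, codon_end=144)
        inside = variant_factory(codon=144)
        outside = variant_factory(codon=145)
        part = apply_region_mask([inside, outside], mask)
        assert part.inside == [inside]
        assert part.outside == [outside]

    def test_missing_coordinate_unassigned(self, variant_factory):
        mask = RegionMask("G", codon_start=1, codon_end=10)
        v = variant_factory(codon=None)
        part = apply_region_mask([v], mask)
        assert part.unassigned == [v]

    def test_partition_conserves_counts(self, variant_factory):
        mask = RegionMask("G", codon_start=50, codon_end=100)
        vs = [variant_factory(codon=c) for c in [1, 50, 75, 100, 101, None]]
        part = apply_region_mask(vs, mask)
        assert len(part.inside) + len(part.outside) + len(part.unassigned) == len(vs)
        assert len(part.inside) == 3

    def test_empty_input(self):
        part = apply_region_mask([], RegionMask("G", codon_start=1, codon_end=5))
        assert part.inside == part.outside == part.unassigned == []

    def test_exon_set_mask(self, variant_factory):
        mask = RegionMask("G", kind="exon_set", included_exons=frozenset({"e1"}))
        v1, v2 = variant_factory(exon="e1"), variant_factory(exon="e2")
        part = apply_region_mask([v1, v2], mask)
        assert part.inside == [v1] and part.outside == [v2]


class TestConstitutiveExons:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["exon_id", "tissue", "expression_value"])

    def test_threshold_zero_keeps_all(self):
        df = self._table([("e1", "cortex", 0.0), ("e2", "cortex", 5.0)])
        assert constitutive_exon_set(df, threshold=0.0) == {"e1", "e2"}

    def test_all_tissues_required(self):
        df = self._table(
            [("e1", "cortex", 9.0), ("e1", "cerebellum", 0.0), ("e2", "cortex", 2.0),
             ("e2", "cerebellum", 2.0)]
        )
        assert constitutive_exon_set(df, threshold=1.0) == {"e2"}

    def test_known_pattern_enumeration(self):
        rng = np.random.default_rng(17)
        tissues = ["t1", "t2", "t3"]
        rows = []
        expected = set()
        for i in range(30):
            exon = f"e{i}"
            vals = rng.uniform(0, 2, size=3)
            rows += [(exon, t, v) for t, v in zip(tissues, vals)]
            if (vals >= 1.0).all():
                expected.add(exon)
        assert constitutive_exon_set(self._table(rows), threshold=1.0) == expected

    def test_empty_table(self):
        assert constitutive_exon_set(self._table([])) == frozenset()


class TestCuratedConstraint:
    def test_zero_observed_with_published_expectation(self):
        """No passing variants against E=12.6: oe=0, 95% bound ~0.238."""
        mask = RegionMask("MAPT", codon_start=1, codon_end=441)
        res = curated_constraint([], mask, expected_gene=12.6)
        assert res.oe == 0.0
        assert res.oe_upper == pytest.approx(-math.log(0.05) / 12.6, abs=1e-9)

    def test_identity_mask_reduces_to_whole_gene(self, variant_factory):
        vs = [variant_factory(codon=c) for c in (3, 200, 499)]
        mask = RegionMask("G", codon_start=1, codon_end=500,
                          mu_region_sum=10.0, mu_gene_sum=10.0)
        res = curated_constraint(vs, mask, expected_gene=4.0)
        assert res.observed == 3
        assert res.expected == 4.0
        assert res.oe == pytest.approx(0.75)

    def test_mu_weighted_region(self, variant_factory):
        vs = [variant_factory(codon=c) for c in (10, 20, 300)]
        mask = RegionMask("G", codon_start=1, codon_end=144,
                          mu_region_sum=3.5, mu_gene_sum=10.0)
        res = curated_constraint(vs, mask, expected_gene=10.0)
        assert res.observed == 2
        assert res.expected == pytest.approx(3.5)

    def test_prnp_style_reference(self):
        """Curated N-terminal region: 6 observed vs 6.06 expected, oe ~ 0.990."""
        res = curated_region_constraint(PRNP)
        assert res.expected == pytest.approx(6.06, abs=1e-9)
        assert res.oe == pytest.approx(6 / 6.06, abs=1e-9)

    def test_mapt_style_reference(self):
        res = curated_region_constraint(MAPT)
        assert res.observed == 0
        assert res.oe_upper == pytest.approx(oe_upper_bound(0, 12.6), abs=1e-12)


class TestVerdicts:
    def test_only_passing_kept(self, variant_factory):
        v1 = variant_factory(pos=1)
        v2 = variant_factory(pos=2)
        v3 = variant_factory(pos=3)
        verdicts = {v1.variant_id: "pass", v2.variant_id: "artefact"}
        assert apply_verdicts([v1, v2, v3], verdicts) == [v1, v3]
        assert apply_verdicts([v1, v2, v3], verdicts, default="not_lof") == [v1]


class TestPositionalDistribution:
    def test_uniform_positions_flat(self):
        """Uniform synthetic positions pass a chi-square GoF test (p > 0.001)."""
        rng = np.random.default_rng(23)
        length = 1000
        positions = rng.integers(1, length + 1, size=1000)
        dist = positional_distribution(positions, length, n_bins=10)
        _, p = stats.chisquare(dist.counts)
        assert p > 0.001
        assert dist.counts.sum() == 1000

    def test_clustered_positions_leave_large_gap(self):
        length, n_bins = 1000, 10
        dist = positional_distribution([5, 17, 60, 99], length, n_bins=n_bins)
        assert dist.max_gap == length - length / n_bins

    def test_empty_input(self):
        dist = positional_distribution([], 300, n_bins=6)
        assert dist.counts.sum() == 0
        assert dist.max_gap == 300
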