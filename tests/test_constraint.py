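"""Constraint ratios, exact Poisson bounds and gene-set comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from lofkit.constraint import (
    compare_gene_sets,
    ks_2sample,
    oe_point,
    oe_upper_bound,
    poisson_rate_upper_bound,
    region_adjusted_expected,
)


def bisect_poisson_upper(observed, alpha, lo=0.0, hi=1e6, tol=1e-10):
    """Independent oracle: solve P(Poisson(lam) <= observed) = alpha by bisection."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stats.poisson.cdf(observed, mid) > alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestOePoint:
    @pytest.mark.parametrize(
        "observed,expected,value",
        [(0, 12.6, 0.0), (5, 5.0, 1.0), (6, 6.06, 6 / 6.06)],
    )
    def test_examples(self, observed, expected, value):
        assert oe_point(observed, expected) == pytest.approx(value, abs=1e-12)

    def test_zero_expected_is_undefined(self):
        assert math.isnan(oe_point(3, 0.0))


class TestOeUpperBound:
    def test_zero_observed_closed_form(self):
        """With O = 0 the exact bound is -ln(alpha)/E analytically."""
        for e in (0.5, 1.0, 12.6, 100.0):
            assert oe_upper_bound(0, e, 0.05) == pytest.approx(
                -math.log(0.05) / e, abs=1e-9
            )
        # alpha = 1/e gives exactly 1/E
        assert oe_upper_bound(0, 7.0, math.exp(-1)) == pytest.approx(1 / 7.0, abs=1e-9)

    @pytest.mark.parametrize("observed", [0, 1, 3, 10, 50])
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.5])
    def test_matches_bisection_oracle(self, observed, alpha):
        oracle = bisect_poisson_upper(observed, alpha)
        assert poisson_rate_upper_bound(observed, alpha) == pytest.approx(
            oracle, abs=1e-7
        )

    def test_worked_example_three_observed(self):
        # lam solving P(X<=3|lam)=0.05 is ~7.754, so the bound on O/E=3/10 is ~0.775
        assert oe_upper_bound(3, 10.0, 0.05) == pytest.approx(0.7754, abs=5e-4)

    def test_upper_bound_exceeds_point(self):
        for o, e in [(0, 12.6), (3, 10.0), (20, 10.0)]:
            assert oe_upper_bound(o, e) > oe_point(o, e)

    def test_decreasing_in_expected_continuous_in_alpha(self):
        es = np.linspace(1, 50, 20)
        bounds = [oe_upper_bound(2, e) for e in es]
        assert all(b1 > b2 for b1, b2 in zip(bounds, bounds[1:]))
        alphas = np.linspace(0.01, 0.5, 50)
        vals = [oe_upper_bound(2, 10.0, a) for a in alphas]
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 0.2  # no jumps


class TestRegionAdjustedExpected:
    def test_identity_and_arithmetic(self):
        assert region_adjusted_expected(10.0, 7.0, 7.0) == 10.0
        assert region_adjusted_expected(10.0, 3.5, 10.0) == pytest.approx(3.5)

    def test_partition_additivity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            parts = rng.dirichlet(np.ones(rng.integers(2, 11)))
            mu_gene = rng.uniform(1, 100)
            e_gene = rng.uniform(0.1, 50)
            adjusted = [
                region_adjusted_expected(e_gene, w * mu_gene, mu_gene) for w in parts
            ]
            assert sum(adjusted) == pytest.approx(e_gene, abs=1e-9)

    def test_region_exceeding_gene_rejected(self):
        with pytest.raises(ValueError):
            region_adjusted_expected(10.0, 11.0, 10.0)


def brute_force_ks(a, b):
    """O(n*m) oracle: sup over pooled points of |F_A(x) - F_B(x)|."""
    d = 0.0
    for x in list(a) + list(b):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


class TestKs:
    def test_identical_samples(self):
        d, p = ks_2sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_2sample([0.1, 0.2], [0.8, 0.9])
        assert d == 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, m = rng.integers(1, 21, size=2)
            a = list(np.round(rng.normal(size=n), 1))  # rounding creates ties
            b = list(np.round(rng.normal(size=m), 1))
            d, _ = ks_2sample(a, b)
            assert d == brute_force_ks(a, b)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=80), rng.normal(0.5, size=60)
        d, p = ks_2sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-3)


class TestCompareGeneSets:
    def test_mean_ci_and_labels(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 1, 200), rng.uniform(0.1, 1.1, 300)
        cmp = compare_gene_sets(a, b, "drug_targets", "all")
        assert cmp.n_a == 200 and cmp.n_b == 300
        lo, hi = cmp.ci_a
        assert lo < cmp.mean_a < hi
        # t-based CI of the mean
        sem = a.std(ddof=1) / math.sqrt(len(a))
        tq = stats.t.ppf(0.975, len(a) - 1)
        assert lo == pytest.approx(a.mean() - tq * sem, abs=1e-12)

    def test_singleton_set_has_no_ci(self):
        cmp = compare_gene_sets([0.5], [0.1, 0.9])
        assert cmp.ci_a is None
        assert 0.0 <= cmp.ks_d <= 1.0
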