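"""Loss-of-function constraint: obs/exp ratios, Poisson bounds, gene-set tests.

The constraint score of a gene (or of a sub-gene region) is the ratio
``O/E`` of the number of distinct pLoF variants observed in a cohort to
the number expected under a neutral mutation model.  Because ``O`` is a
count, an exact one-sided Poisson (Garwood) upper bound quantifies how
much constraint the data can exclude; for ``O = 0`` the 95% bound is
``-ln(0.05)/E``.  Expected counts computed for a whole transcript are
rescaled to a sub-region by the ratio of summed per-site mutation
frequencies, which is additive over any partition of the transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ConstraintResult:
    """obs/exp constraint for one gene or region.

    ``oe`` and ``oe_upper`` are NaN and ``undefined`` is True when the
    expected count is zero.
    """

    gene_or_region_id: str
    observed: int
    expected: float
    oe: float
    oe_upper: float
    alpha: float = 0.05
    undefined: bool = False


@dataclass
class GeneSetComparison:
    """Two-sample comparison of constraint distributions.

    Carries the per-set mean obs/exp with a 95% confidence interval of
    the mean (t-based; ``None`` when a set has fewer than two values)
    and the two-sided Kolmogorov-Smirnov statistic with its asymptotic
    p-value.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    ci_a: Optional[tuple[float, float]]
    ci_b: Optional[tuple[float, float]]
    ks_d: float
    ks_p: float


def oe_point(observed: int, expected: float) -> float:
    """Point estimate ``O/E``; NaN when ``expected`` is zero."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    if expected == 0:
        return math.nan
    return observed / expected


def poisson_rate_upper_bound(observed: int, alpha: float = 0.05) -> float:
    """Exact one-sided ``1 - alpha`` upper bound on a Poisson rate.

    Solves ``P(Poisson(lam) <= observed) = alpha`` for ``lam``, which by
    the Poisson/chi-square identity is ``chi2.ppf(1 - alpha,
    2*(observed + 1)) / 2``.  For zero observations this reduces to
    ``-ln(alpha)``.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return 0.5 * stats.chi2.ppf(1.0 - alpha, 2 * (observed + 1))


def oe_upper_bound(observed: int, expected: float, alpha: float = 0.05) -> float:
    """One-sided ``1 - alpha`` upper confidence bound on ``O/E``.

    Examples
    --------
    A region with 0 observed and 12.6 expected pLoF variants has a 95%
    upper bound of ``-ln(0.05)/12.6`` = 0.2378, i.e. constraint cannot
    be distinguished from ~24% of the neutral expectation.
    """
    if expected == 0:
        return math.nan
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    return poisson_rate_upper_bound(observed, alpha) / expected


def constraint_result(
    observed: int,
    expected: float,
    gene_or_region_id: str = "",
    alpha: float = 0.05,
) -> ConstraintResult:
    """Bundle point estimate and upper bound into a :class:`ConstraintResult`."""
    undefined = expected == 0
    return ConstraintResult(
        gene_or_region_id=gene_or_region_id,
        observed=int(observed),
        expected=float(expected),
        oe=oe_point(observed, expected),
        oe_upper=oe_upper_bound(observed, expected, alpha),
        alpha=alpha,
        undefined=undefined,
    )


def region_adjusted_expected(
    expected_gene: float, mu_region_sum: float, mu_gene_sum: float
) -> float:
    """Rescale a whole-gene expected count to a sub-region.

    Multiplies ``expected_gene`` by the ratio of the summed mutation
    frequencies of all possible pLoF variants in the region to the sum
    over the entire transcript.  Additive over any partition of the
    transcript into disjoint regions.
    """
    if mu_gene_sum <= 0:
        raise ValueError("mu_gene_sum must be positive")
    if mu_region_sum < 0:
        raise ValueError("mu_region_sum must be non-negative")
    if mu_region_sum > mu_gene_sum:
        raise ValueError("mu_region_sum exceeds mu_gene_sum")
    return expected_gene * (mu_region_sum / mu_gene_sum)


def ks_2sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` where ``D`` is the exact supremum of the absolute
    difference between the two empirical CDFs and ``p`` the asymptotic
    two-sided p-value (Kolmogorov distribution of ``sqrt(nm/(n+m)) D``).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / n
    cdf_b = np.searchsorted(b, pooled, side="right") / m
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    # asymptotic two-sided p-value: survival function of the two-sample
    # Kolmogorov distribution at D with effective size nm/(n+m)
    en = int(round(n * m / (n + m)))
    p = float(np.clip(stats.kstwo.sf(d, max(1, en)), 0.0, 1.0))
    return d, p


def _mean_ci(values: np.ndarray, level: float = 0.95) -> Optional[tuple[float, float]]:
    n = values.size
    if n < 2:
        return None
    mean = float(values.mean())
    sem = float(values.std(ddof=1)) / math.sqrt(n)
    tq = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return (mean - tq * sem, mean + tq * sem)


def compare_gene_sets(
    oe_values_a: Sequence[float],
    oe_values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> GeneSetComparison:
    """Compare two sets of obs/exp values (forest-plot means + KS test)."""
    a = np.asarray(oe_values_a, dtype=float)
    b = np.asarray(oe_values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene sets must be non-empty")
    d, p = ks_2sample(a, b)
    return GeneSetComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_a=_mean_ci(a),
        ci_b=_mean_ci(b),
        ks_d=d,
        ks_p=p,
    )
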