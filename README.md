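# lofkit

Analysis toolkit for human **loss-of-function (LoF) genetic variation**:
given a cohort's predicted LoF (pLoF) variants, how common are carriers
of one broken copy of each gene, how rare are "human knockouts" with
both copies inactivated, how many individuals would you need to
sequence to find (or statistically rule out) such knockouts, and how
strongly has natural selection purged LoF variants from a gene?

It is aimed at statistical geneticists and target-validation teams who
work with aggregated exome call sets (per-variant allele counts plus
LoF annotation flags) and per-gene expected-variant counts from a
neutral mutation model.

## The model

For a gene, let `q` be the proportion of individuals carrying **no**
pLoF allele. The cumulative pLoF allele frequency is estimated under
Hardy-Weinberg proportions as

```
p = 1 − sqrt(q)
```

which conservatively treats two different pLoF variants in the same
individual as being in *cis* (one allele). Genotype frequencies in the
absence of selection are then:

| quantity | outbred / bottlenecked | consanguineous (autozygous fraction `a`) |
|---|---|---|
| heterozygote | `2p(1−p)` | `2p(1−p)` |
| two-hit (hom. + compound het.) `f` | `p²` | `(1−a)p² + ap` |

A bottlenecked population uses the same closed forms with a
population-specific `p`; the distorted founder spectrum is produced by
the bundled simulator. Default `a = 0.058`, the mean autozygous genome
fraction of individuals with second-cousin-or-closer parents (whose
offspring have inbreeding coefficient `F = 1/64`, which
`lofkit.pedigree` derives by path counting).

Sample-size projections: discovery of a two-hit individual is expected
at `N = ceil(1/f)`; inferring that the two-hit genotype is lethal from
observing none requires `N = ceil(ln α / ln(1−f))` (≈ 3× larger at
α = 0.05).

Constraint: for observed count `O` and neutral expectation `E`, the
score is `O/E` with an exact one-sided Poisson (Garwood) upper bound —
for `O = 0` the 95% bound is `−ln(0.05)/E`. Expectations restrict to
sub-gene regions (codon intervals, expression-defined exon sets) via
mutation-frequency weights, and gene sets are compared with two-sample
Kolmogorov–Smirnov tests and t-based confidence intervals of the mean.

Everything is validated against a synthetic cohort generator
(`lofkit.synthetic`) that simulates per-haplotype variant carriage
under all three population structures.

## Worked example

```python
import lofkit as lk

summaries = [
    lk.CarrierSummary("HTT_like",   125_748, 120),  # 120 carriers among 125,748
    lk.CarrierSummary("PRNP_like",  125_748, 85),
    lk.CarrierSummary("SHORT_like", 125_748, 3),
    lk.CarrierSummary("UNSEEN",     125_748, 0),
]
res = lk.KnockoutProspectsModel(summaries, autozygosity_a=0.058).fit()
print(res.summary())
```

```
Knockout prospects
==================
genes: 4   structures: outbred, bottlenecked, consanguineous
autozygosity a = 0.058   alpha = 0.05

genes with >=1 pLoF carrier: 3 (75.0%)
        outbred: median two-hit freq 5.72e-08; median discovery N 8,751,400
   bottlenecked: median two-hit freq 5.72e-08; median discovery N 8,751,400
 consanguineous: median two-hit freq 1.02e-05; median discovery N 50,727
```

The median gene here has an expected two-hit frequency of ~6 per 100
million in outbred populations — discovery would need ~8.8 million
individuals — while recruiting consanguineous individuals cuts the
required sample size by more than two orders of magnitude (~51,000).
`res.frame` holds the per-gene rows (`p`, `het_freq`, `two_hit_freq`,
`n_discovery`, `n_lethality`); genes with no carriers are flagged
censored and their sample sizes reported as unattainable (`inf`).

Constraint with exact Poisson bounds:

```python
cm = lk.ConstraintModel([0, 6], [12.6, 6.06],
                        ids=["MAPT:brain-exons", "PRNP:1-144"]).fit()
print(cm.summary())
```

```
         gene_id  observed  expected    oe oe_upper  undefined
MAPT:brain-exons         0     12.60 0.000    0.238      False
      PRNP:1-144         6      6.06 0.990    1.954      False
```

Zero observed against 12.6 expected bounds obs/exp below 23.8% — the
data cannot yet distinguish full LoF intolerance from ~¼ of neutral —
whereas 6 observed against 6.06 expected (oe = 0.99) is an
unconstrained region.

A `lofkit` console script exposes the same stages
(`simulate`, `caf`, `project`, `roadmap`, `constraint`, `compare`,
`curate`, `prevalence`, `run-all`); `lofkit run-all --out-dir out`
runs the fully simulated pipeline deterministically from a YAML config.

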