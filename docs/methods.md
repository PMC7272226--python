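# Methods

## Cumulative allele frequency

Per gene, the estimator works from carrier counts, not allele counts:
`q = (n_individuals − n_carriers) / n_individuals` and
`p = 1 − sqrt(q)`. Two consequences are deliberate:

* **cis conservatism** — an individual with several distinct pLoF
  variants contributes one carrier, so `p` is a lower bound relative to
  the per-variant allele-frequency sum (they agree when no individual
  carries two variants in trans);
* **censoring** — a gene with zero carriers gets `p = 0` and
  `caf_censored = true`; absence of evidence at current sample size is
  not evidence of intolerance.

A singleton gene yields `p = 1 − sqrt(1 − 1/n)` rather than the
allele-counting convention `1/(2n)`; the two agree to first order
(relative difference `~1/(4n)`) and one formula keeps the code uniform.
No correction is applied for the fact that singleton variants' true
frequencies are on average below their nominal frequency.

## Genotype frequencies and population structure

Heterozygote frequency is `2p(1−p)` under every structure. Two-hit
frequency is `p²` for outbred and bottlenecked populations — the
bottleneck changes *which* `p` you plug in (a population-specific
estimate), not the closed form — and `(1−a)p² + ap` for consanguineous
individuals, obtained by treating each locus as identical-by-descent
with probability `a` (the genome-wide mean autozygous fraction).
Modelling autozygosity as a per-gene IBD coin flip reproduces that
expectation exactly; per-individual variation in `a` is not modelled
because only the cohort mean is characterised. Selection against
two-hit genotypes is assumed absent: projections presume the knockout
is tolerated.

Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `autozygosity_a` | 0.058 | mean autozygous genome fraction in second-cousin-or-closer offspring (reported mean 0.05766) |
| `alpha` | 0.05 | one-sided level for lethality inference and Poisson bounds |
| `maf_caf` | 0.05 | strict MAF cutoff for variants entering CAF estimation |
| `maf_constraint` | 0.001 | strict MAF cutoff for variants counted toward constraint |
| `pli_cutoff` | 0.9 | strict threshold for "likely haploinsufficient" |
| `consanguineous_world_fraction` | 0.104 | share of the world population with second-cousin-or-closer parents (context constant) |

MAF thresholds are strict (`<`), matching the conventions the filters
were defined with.

## Sample-size projections

Discovery uses the expected-count rule: smallest `N` with `N·f ≥ 1`,
i.e. `ceil(1/f)`. An alternative median rule (smallest `N` with
`P(≥1 observed) ≥ 1/2`, smaller by a factor `ln 2`) is exposed via
`discovery_rule="median"`; the expected-count rule is the default
because the natural comparison is between cohort-size lines and
expected-frequency histograms. Lethality inference is the smallest `N`
with `(1−f)^N ≤ α`, i.e. `ceil(ln α / ln(1−f))`. For small `f` the
ratio lethality/discovery approaches `−ln α ≈ 3.0` at α = 0.05. For
`f` near 1 the two rules can cross (at `f = 0.99`, discovery N = 2 but
a single knockout-free individual already rejects at 5%); the
"lethality ≥ discovery" ordering is therefore only asserted for
`f ≤ 0.5`, far above any realistic two-hit frequency. `f = 0` is
reported as unattainable (infinity), never an exception.

## Constraint

`oe = O/E` with an exact one-sided Poisson (Garwood-style) upper bound:
the rate `λ_up` solving `P(Poisson(λ) ≤ O) = α`, computed via the
chi-square identity `λ_up = χ²_{1−α, 2(O+1)}/2` and divided by `E`.
For `O = 0` this is `−ln α / E` analytically — the implementation and
the closed form agree below 1e-9, and tests also cross-check a
bisection solver on the Poisson CDF. The likelihood-ratio interval
variant used by some constraint pipelines is out of scope. `E = 0`
yields a flagged undefined result rather than an exception.

Region-restricted expectations multiply the whole-gene `E` by the
ratio of summed per-site mutation frequencies (region over transcript);
the operation is additive over any partition of the transcript, and an
identity mask reproduces the whole-gene result exactly. Codon
intervals are 1-based, inclusive on both ends (a mask over codons
1–144 contains codon 144; codon 145 is outside). Constitutive exon
sets require expression at or above a threshold (default 1 expression
unit, configurable — no published cutoff exists for the motivating
analysis) in *every* required tissue. Manual curation verdicts are
consumed as a per-variant column (`pass`, `artefact`,
`annotation_error`, `not_lof`), never re-derived.

Gene-set comparison: the KS `D` is the exact supremum of the ECDF
difference over pooled points (verified against an O(n·m) brute-force
oracle); its p-value is the asymptotic two-sided value from the
two-sample Kolmogorov distribution at effective size `nm/(n+m)`,
matching scipy's convention. Means carry t-based 95% confidence
intervals, omitted for sets of size one.

The bundled curated-region references (`lofkit.reference`) carry
published observed/expected pairings for two archetypes — a
brain-restricted transcript with `E = 12.6`, `O = 0`, and a
single-exon N-terminal region with `O = 6` against an adjusted
`E = 6.06`. The per-codon mutation weights in the latter are
synthetic (uniform over the 253-codon frame) with the transcript
expectation chosen consistently with the published region pairing;
real weights would come from a trinucleotide mutation-rate model,
which is an upstream input, not part of this package.

## Roadmap classification

Sequential first-match rules: known Mendelian disease association →
reported two-hit genotype → pLI > 0.9 → CAF = 0 → pLoF observed. The
ordering makes the partition exact (every gene in exactly one
category) and stable: toggling a lower-priority attribute cannot move
a gene matched by a higher-priority rule. Missing pLI skips the
haploinsufficiency rule with a warning; missing pLI with `p = 0` falls
through to "pLoF not observed" (the data-availability reading of the
sequence). Source-cohort provenance behind the two-hit flag is not
modelled; a single merged flag is consumed.

## Synthetic cohort generator

The generator defines the study conditions for every test:

* **catalog** — true CAFs log-uniform over `[1e-6, 1e-2]` (spanning
  the orders of magnitude of a large exome database without asserting
  its exact distribution); coding lengths log-normal around ~470
  codons; one variant per ~150 codons; within a gene ≥80% of variants
  are near-minimal frequency ("ultra-rare bulk") with a few
  higher-frequency variants carrying the rest of the mass, mimicking a
  singleton-dominated site-frequency spectrum; pLI drawn from a
  bimodal Beta mixture; `expected_lof` scales with coding length with
  ±50% noise.
* **cohort** — per gene, each haplotype carries each variant
  independently with its frequency (no linkage disequilibrium, no
  phasing ambiguity); bottleneck: a founder pool of `H` haplotypes is
  drawn once and every cohort haplotype copies a uniform founder (so
  variants absent from the pool have cohort allele count 0);
  consanguinity: per individual and gene, the second haplotype is an
  IBD copy of the first with probability `a`.

What the generator does **not** emulate: recombination and LD,
pedigree structure, per-individual variation in `a`, sequencing error,
genotype likelihoods, population stratification, or the empirical
gnomAD frequency spectrum. Passing tests therefore demonstrate
internal consistency of the estimators with their assumed sampling
model — convergence of empirical carrier/two-hit fractions to the
closed forms within 3 binomial standard errors — not calibration
against real cohorts. Likewise the pipeline's simulated obs/exp
values exercise plumbing and set comparisons; `expected_lof` is an
independent metadata draw, so simulated constraint distributions are
not calibrated to real ones.

Determinism: all randomness flows from `numpy` Generators seeded from
the user seed (per-gene child seeds via `SeedSequence.spawn`), and the
pipeline writes version/seed/config-hash headers, making repeat runs
byte-identical.

## Problem sizes and numerical choices

Validation runs use 100,000 individuals for CAF recovery (p = 0.01),
200,000 for outbred two-hit convergence (p = 0.02), 2,000,000 for the
consanguineous closed form (p = 0.001, a = 0.058), and 150 genes ×
2,000 individuals × 3 structures for end-to-end determinism; the whole
suite runs in a few seconds on one core. Degenerate inputs are pinned
down explicitly: a degenerate CAF range returns its bound exactly;
empty cohorts/catalogs produce valid empty outputs; `p = 0` genes are
censored, not errors.

## Known limitations

* The CAF estimator inherits every caveat of frequency-only reasoning:
  unobserved ultra-rare alleles, uncurated false-positive pLoF calls
  (which inflate `p`), and the cis assumption (which deflates it).
* Two-hit projections assume neutrality of the knockout genotype;
  where it is lethal or severely selected they overestimate the
  discoverable frequency — that is precisely what the lethality
  sample size is for.
* The consanguineous model uses a single mean `a`; real cohorts mix
  inbreeding levels.
* The KS p-value is asymptotic; for very small gene sets prefer the
  exact statistic comparison the tests use.
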