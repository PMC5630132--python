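# Methods

## Model and procedure

The analysis is a carrier-collapsing (CAST-style) burden test for a panel
of candidate genes in a case–control sample, followed by single-variant
tests and a pooled multi-cohort replication step.

**Counting.** For each gene, the aggregated count is one observation per
(sample, qualifying site) pair with a carrier genotype: a heterozygote or
homozygote contributes 1 per site, and a sample carrying two distinct
qualifying variants contributes 2. Burden denominators are the post-QC
group sizes; single-variant denominators are the per-site non-missing call
counts (samples uncalled at a site are not at risk for it). The literature
is not unanimous on whether a homozygote should count once or twice and
whether a multi-variant carrier should be collapsed to one observation;
because rare-variant carriers are overwhelmingly single-site heterozygotes
the three conventions almost always coincide, and all three are available
(`count_rule` = `per_site` (default) / `alleles` / `per_sample`). A count
exceeding its group size violates the 2×2 invariants and raises rather
than silently producing an invalid table.

**Inference.** The test is the one-sided Fisher exact test with the
alternative fixed a priori as enrichment in cases (the design's causal
hypothesis for disruptive and missense variants; a one-sided exact test
also behaves better than logistic regression when carrier counts are
single digits). The tail probability is computed from hypergeometric
point masses conditioned on all margins, via log-factorials (`gammaln`)
with a log-sum-exp reduction; agreement with exact integer-arithmetic
enumeration is ~1e-13 relative. A table with zero total observations
returns p = 1. The odds ratio is the unconditional sample OR on
carriers-vs-non-carriers cells with the Woolf log-scale CI at z = 1.959964;
any zero cell renders OR and CI undefined — no Haldane–Anscombe continuity
correction is applied, so degenerate tables are reported as "n/a" instead
of an arbitrary finite estimate. Multiplicity over the m candidate genes
uses Bonferroni (`min(1, m·p)`).

**Qualifying variants.** A site qualifies when (i) its consequence class
is allowed — protein-disrupting (stop gained/lost, start lost, frameshift,
canonical splice ±2 bp) or missense by default; (ii) its reference-panel
MAF is ≤ 0.01, inclusive, where the MAF is the folded alternate-allele
frequency `min(af, 1−af)`; and (iii) it survived site QC. A variant absent
from the reference panel is treated as MAF 0: novel variants are the
rarest class, and treating absence as "unknown, exclude" would remove
precisely the variants a rare-variant design is built around. The
consequence vocabulary is a configurable lexicon (annotation pipelines
disagree on strings; unknown strings degrade to `other` with a logged
warning rather than an error).

**QC ordering.** Sample call-rate filtering runs first, over all assayed
sites; site filtering runs second, on the reduced matrix, and requires the
call rate to reach the threshold within cases *and* within controls
separately (per-group filtering protects against a site that is well
genotyped overall but differentially missing in one group). Both
comparisons are inclusive: a rate of exactly 0.95 passes. Filters are
idempotent and monotone in the threshold, and the tests pin the ordering.
The per-group reading of the site rule is the most literal one; a pooled
reading would differ only for sites near the boundary, and the per-group
version is the stricter of the two.

**Coverage summary.** Per-gene "coverage" is the percentage of targeted
coding positions represented by retained variant sites (a retained site
covers its reference span intersected with the gene's target intervals).
In a real study this quantity derives from sequencing depth and is not
reproducible from genotypes alone; here only the computation is defined
and tested.

**Multi-cohort combination.** Replication pooling is naive count addition
over pairwise-disjoint cohorts followed by a single exact test on the
pooled table — deliberately *not* a stratified (e.g.
Cochran–Mantel–Haenszel) test, which would be a different statistic from
the one this package sets out to compute. Disjointness is enforced by the
caller either with explicit overlapping-sample-id sets (recounted from
genotypes) or by replacing a cohort that is subsumed by another dataset
with its unique (non-overlapping) subset.

## Synthetic cohorts

The generator emulates a multi-cohort targeted-sequencing study: ~13 genes
each with a handful of rare qualifying sites plus non-qualifying sites
(synonymous, or missense too common to pass the MAF filter), 1886 cases
and 1700 controls across six cohorts by default, and MCAR missingness at
2% per sample and 1% per site (an optional extra case-specific rate exists
to exercise differential-missingness QC; default off).

Each subject carries at most one qualifying variant per gene,
heterozygous — matching the singleton-dominated spectra of rare-variant
panels. Gene-level control carrier frequency `cf` is split across sites by
a skewed Dirichlet(0.5) weight vector (a few recurrent variants, many
near-singletons); case carrier probability is the odds transform
`cf·OR / (1 − cf + cf·OR)`, the simplest model consistent with OR-based
reporting (no liability threshold). Non-qualifying sites get independent
Hardy–Weinberg genotypes at their panel frequency. Default gene parameters
(carrier frequencies 1–52 per 1700 controls, ORs 0.85–5.93) span the range
a candidate-gene panel of this kind observes, with most genes null.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, population stratification, relatedness,
platform/batch effects, depth-driven (informative) missingness, and
homozygous rare genotypes. Passing tests therefore demonstrate the
correctness and calibration of the pipeline under idealised sampling, not
robustness to confounding present in real cohorts.

## Numerical and design choices

- Internal coordinates are 1-based inclusive (VCF POS convention); BED is
  converted on read/write. Multi-allelic VCF records are split per
  alternate allele, and a genotype carrying a *different* alt counts 0 at
  the split site; any genotype with a no-call allele is missing.
- Phenotype status tokens case/control, CA/CO, 1/0, affected/unaffected are
  normalised at read; anything else is an error naming the token.
- p-values are rendered in scientific notation at 2 significant figures and
  OR/CI at 2 decimals (the conventional presentation); full precision stays
  on the result objects.
- Indel normalisation (left-alignment) is assumed done upstream; keys are
  matched on (chrom, pos, ref, alt) exactly.
- Monte-Carlo problem sizes: null calibration runs 2000 replicates at
  400 + 400 subjects over a 6-gene null panel — conservativeness of the
  exact test under discreteness holds at any sample size, so the smaller
  cohort is a pure efficiency choice; parameter recovery runs 400
  replicates at the full 1886/1700 scale with no missingness (the
  odds-ratio estimate is only unbiased for the configured OR when no
  carriers are lost to masking), and its matched null uses 200 replicates.

## Known limitations

- The burden test has no covariate adjustment (age, sex, principal
  components); that is inherent to the exact-test design, not an omission.
- Pooled multi-cohort testing ignores between-cohort frequency
  heterogeneity; a stratified or meta-analytic variant is out of scope.
- Coverage percentages from real depth data cannot be reproduced from
  genotype matrices; the reported quantity is the retained-site position
  coverage defined above.
- The single-variant per-site denominators depend on which samples were
  called at that site; two studies printing the same carrier counts can
  legitimately report slightly different p-values if their call sets
  differ.
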