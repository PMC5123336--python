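# Methods

## Problem setting

Disease-mutation databases accumulate assertions whose evidence predates
modern population-scale frequency resources.  Two observations contradict a
claim that a variant causes a (fully penetrant) Mendelian disease: an
allele frequency too high for the disorder, and homozygous occurrence in an
individual who lacks the phenotype of a recessive disorder.  Cohorts from
populations with high consanguinity are especially informative for the
second observation — autozygosity exposes rare alleles in homozygous form
at rates far above Hardy–Weinberg — but the same cohorts are recruited
through diseased probands, which biases frequency estimates upward.  The
package operationalizes both evidence types and the correction for the
recruitment bias.

## Cohort frequency estimation

Let `no_het`, `no_hom`, `no_screened` be the heterozygote, homozygous-
alternate and total genotyped counts at a site.  The corrected estimator

    SGP_AF = no_het / (2 * (no_screened - no_hom))

removes every homozygous-alternate individual from both numerator and
denominator.  Proband ascertainment adds homozygotes, not heterozygotes, so
adding k ascertained homozygotes maps (no_hom, no_screened) to
(no_hom + k, no_screened + k) and leaves the estimator fixed — exactly, not
approximately, which is why both estimators are computed with
`fractions.Fraction` and converted to decimal only at output.  The naive
baseline `(no_het + 2*no_hom) / (2*no_screened)` is strictly increasing in
k and is reported alongside for comparison.

Under the inbreeding genotype model (below), the estimator's large-sample
value is

    E[SGP_AF] -> 2p(1-p)(1-F) / (2(1 - p^2 - Fp(1-p)))

obtained by substituting the genotype-class expectations into the formula.
For p ≤ 0.05 this differs from p by a relative bias of order p (the
estimator conditions on non-homozygotes, slightly depressing the allele
count), which is immaterial at the 1% and 5% decision thresholds.  The
degenerate case `no_screened == no_hom` (every screened individual
homozygous) raises a dedicated error; the decision engine converts it into
an unchanged outcome with a per-record warning.

## Decision rules

The four criteria are evaluated in fixed precedence C1 → C2 → C3 → C4,
first match wins, which realizes them as disjoint strata:

* C1: some public resource reports AF ≥ `af_benign_public` (default 0.05).
  Resources are scanned in the order 1000 Genomes, ExAC, Kaviar; the first
  crossing source is recorded as provenance, the maximum AF alongside.
* C2: SGP_AF ≥ `af_cohort_common` (0.05) while no public AF reaches 0.05.
* C3: SGP_AF ≥ `af_cohort_low` (0.01) and at least one homozygote in an
  individual lacking the reported phenotype.
* C4: SGP_AF < 0.01 with such a homozygote — the "BS2-only" designation,
  kept distinct from benign because the frequency arm (BS1) is absent.

C1–C3 thresholds are inclusive (≥), reflecting "larger than or equal to"
semantics; the BRCA screen uses a strict > 0.01.  Thresholds supplied as
floats are interpreted through their decimal representation (0.05 means the
rational 1/20) before comparison with the exact rational cohort estimate,
so boundary cases resolve the way the stated percentages imply.

Missing evidence is asymmetric by design: a variant absent from a public
resource fails every ≥ test (absence cannot support benign frequency
evidence) and satisfies every < requirement (C2's "below 5% in public
databases").  A variant with no cohort row has neither cohort frequency nor
homozygote evidence and can only match C1.

Phenotype matching is consumed as a precomputed per-variant count
(`hom_phenotype_free`); adjudicating whether an individual's phenotype
matches a disease label is a clinical judgement that the engine does not
attempt to replicate.

The inheritance-aware ACMG rule (dominant: public AF > 0.01; recessive or
unknown: public AF > 0.01 plus at least one reported homozygote) is emitted
as an advisory column only.  The stand-alone 5% rule and the 1%
inheritance-aware rule are conceptually distinct evidence strengths; the
engine never merges them, so the criterion labels stay interpretable.

Alternate-allele frequencies are used as reported and are not folded to
minor-allele frequency: a morbid assertion names a specific alternate
allele, and folding would let the reference allele's frequency stand in for
it.  For alleles near 50% this is the one place the package's reading of
"MAF" thresholds could differ from a folded reading.

## BRCA screen and reciprocal check

BRCA Exchange VOUS and likely-pathogenic assertions are triaged on two
axes: cohort SGP_AF > `brca_maf` (0.01, strict) and `fanconi_free_hom ≥ 1`
(homozygotes lacking Fanconi anemia, the fully penetrant biallelic BRCA2
phenotype).  Both → benign; frequency only → frequent-only; zygosity only →
BS2-only; neither → unchanged.  "Observed in homozygosity" is read as
at-least-once.  Pathogenic-class assertions are not triaged by the screen;
they flow to the reciprocal check, which flags any pathogenic assertion
homozygous in a phenotype-free individual as a violation for manual review
and lists homozygotes in phenotype-positive individuals as consistent
corroboration.

## Quality gate

Cohort observations enter the engine only if called by both the Ion Proton
and Illumina platforms, or called by Proton alone as an SNV with quality
score ≥ 1000, depth ≥ 150, and Sanger confirmation ("minimum" read as
inclusive).  Multi-nucleotide substitutions are conservatively treated as
non-SNV for the strict route.  Sanger confirmation is a per-variant flag.
Cohort rows with no quality record are excluded by default (configurable).
The filter reports the fraction of retained rows accepted via cross-
platform concordance; the synthetic generator plants this near 0.99,
matching what dual-platform cohorts exhibit in practice.

## Synthetic cohort generator

Each site is an independent biallelic locus.  Genotypes follow the
inbreeding mixture: with probability F the two alleles are identical by
descent (the genotype is a single allele draw), otherwise Hardy–Weinberg,
giving hom_alt = p² + Fp(1−p), het = 2p(1−p)(1−F), hom_ref = (1−p)² +
Fp(1−p); these are computed as exact rationals and sum to 1 identically.
Defaults: 5849 background individuals (the cohort scale of a national
Mendeliome assay) and F = 0.0625, the expected inbreeding coefficient of
first-cousin offspring — a modeling default for a highly consanguineous
population, since no empirical cohort-wide F is published.  Proband
enrichment is additive: appended individuals are homozygous-alternate and
phenotype-positive, so `hom_phenotype_free` counts background homozygotes
only and the estimator invariance is exact by construction.

Planted classes are realized by bounded rejection sampling (default 1000
draws per site) from class-specific regimes: C1 sites get a public AF drawn
in [0.06, 0.50]; C2 sites p = 0.12 with realized SGP_AF ≥ 0.05 and public
AF < 0.05; C3 sites p = 0.03 with realized SGP_AF in [0.01, 0.05) and ≥ 1
background homozygote; C4 sites p = 0.002 with SGP_AF < 0.01 and ≥ 1
homozygote; NONE sites p = 0.002 with no homozygotes; pathogenic-consistent
sites a clean background plus two appended diseased homozygotes.  The
Pathogenic assertion class is assigned only to strata constructed without
phenotype-free homozygotes, so the expected reciprocal-violation set on
planted fixtures is exactly empty.  Draw streams derive from
`(seed, site_index)`, making bundles byte-identical across runs.

What the generator does not emulate: linkage and shared haplotypes between
sites, realistic mutation spectra, pedigree structure, genotyping error,
and population stratification.  Passing the planted-truth tests therefore
demonstrates that the decision logic is implemented correctly under the
stated genotype model, not that real cohort data would be free of the
joining, phenotype-matching and calling ambiguities those features create.

## Numerical and format choices

Variant keys are hg19-named, 1-based, left-trimmed minimal representations
(shared suffix trimmed before shared prefix, one anchor base retained for
indels) — the dominant VCF convention, making cross-source joins
deterministic; normalization is idempotent and preserves the represented
edit.  Duplicate assertions for one variant are legitimate (multiple
submissions) and each is scored; duplicate cohort/annotation/quality rows
for one key are an error.  HGMD DP/DFP classes are parsed but excluded from
scoring unless enabled.  The CADD "damaging" threshold for the prediction
summary (phred ≥ 20, inclusive) is a convention, stated in the report
header.  All outputs are deterministic: no timestamps, JSON evidence
serialized with sorted keys, input checksums recorded in the run log.

## Problem sizes used in the checks

The test and acceptance workloads are sized for quick desk-scale runs:
10,000 random count configurations for the exact-invariance property,
20 replicate cohorts of 100,000 individuals for the large-sample
expectation (within three standard errors of the closed form), 600 planted
sites (100 per class) at the 5849-individual scale for full-pipeline label
recovery, and 10,000 randomized records for the engine-versus-oracle
comparison.  The complete suite runs in a few seconds.

## Known limitations

Autosomal biallelic model only: no sex-chromosome hemizygosity, no
multi-allelic reconciliation (each alternate allele is its own key), no
liftover between genome builds, and no aggregation of the broader ACMG
criterion set beyond the frequency/zygosity evidence implemented here.
Per-assay denominators (panel vs exome subsets) are not modeled; cohort
counts are pooled.
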