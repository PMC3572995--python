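# Methods

`dlahap` implements the analysis chain of a single-breed canine MHC (DLA)
class II case-control study: sequence-based typing of exon-2 consensus reads,
homozygote-seeded three-locus haplotype phasing, and graded-control
contingency statistics, plus a synthetic breed-cohort generator that makes
every stage verifiable without external data. This note records the models,
the numerical choices, and the places where the design was genuinely open.

## Sequence-based typing

Each dog yields one single-direction Sanger consensus per locus (reverse
strand for DRB1 and DQA1, forward for DQB1). A diploid consensus is modelled
as the position-wise *superposition* of the two allele sequences: identical
bases pass through, differing bases become the two-base IUPAC code. Typing
inverts this by exact matching: the candidate set for a read is every
unordered pair of library alleles (identical pairs allowed) whose
superposition equals the read.

Choices:

- **Exact equality, no mismatch tolerance.** The consensus is assumed
  base-called and manually curated upstream; an error model would belong to a
  chromatogram-level tool, which this is not.
- **Reads containing 3- or 4-base codes (N, V, ...)** are accepted as input
  but reported `unresolvable`: a diploid superposition can only produce 1- or
  2-base codes, so such a read cannot be explained by any allele pair.
- **Genuine ambiguity** (several pairs superpose to the same read) is
  reported, not silently resolved. An optional prior-frequency table can
  promote the most frequent pair; ties remain ambiguous.
- Antisense reads are reverse-complemented under IUPAC complement rules
  (R<->Y, K<->M; S and W self-complementary) before matching; the operation
  is idempotent.

## Haplotype phasing

The three loci sit in one tightly linked block (no recombination is
modelled), and within a breed haplotype diversity is small, so a conservative
Clark-style parsimony procedure is used:

1. **Full homozygotes (h = 0)** each carry two copies of one unambiguous
   haplotype; these seed the established pool.
2. **Single-locus heterozygotes (h = 1)** phase deterministically against
   their homozygous background, confirming and extending the pool.
3. **Remaining dogs (h >= 2)** have 2^(h-1) consistent haplotype pairs. A dog
   is phased when exactly one pair has both members in the pool. When no
   fully pooled pair exists, a parsimony fallback admits at most one novel
   haplotype per dog (the partner of a pooled haplotype), and only when that
   choice is unique; two novel haplotypes in one dog leave it unresolved.

To make the procedure deterministic and order-independent, processing is by
heterozygosity stratum, and the h >= 2 stage is iterated to a fixed point
with each pass evaluated against the pool frozen at the pass start. Novel
(parsimony) admissions happen only after pool-only inference stalls. Dogs
with several fully pooled consistent pairs are reported `ambiguous` (with the
pairs listed; optional ranking by the product of current pool counts), and
dogs with a missing locus are excluded from phasing.

One property worth stating precisely: adding a fully homozygous dog whose
haplotype is already pooled never changes existing assignments. Adding a
homozygote for a *novel* haplotype, however, can demote a previously
uniquely-phased dog to ambiguous, because the new pool member can create a
second consistent pair — the randomized tests exhibit such cases, and the
exhaustive-enumeration oracle agrees. This is inherent to pool-based
parsimony phasing, not an implementation artifact.

An exhaustive brute-force oracle (raw enumeration of ordered allele picks,
fixed-point closure) lives in the test suite; on 500 random small cohorts the
algorithm's uniquely-phased set and pool match it exactly.

## Association statistics

Two counting units are explicit and never mixed: **chromosome-level** tables
(each phased dog contributes two chromosomes; the `2n` convention) for
haplotype and allele frequencies and their odds ratios, and **dog-level**
tables for carrier/dose analyses (0/1/2 copies of the target, 0-copy class as
baseline with OR fixed at 1).

- **Odds ratio**: cross-product (a·d)/(b·c). Tables with a zero cell get the
  Haldane–Anscombe +0.5 added to every cell for the point estimate and CI;
  the raw table is retained and the adjustment flagged.
- **Yates chi-squared**: n(|ad−bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d)), with the
  correction floored so the statistic is 0 when |ad−bc| <= n/2. The p-value
  is the upper tail of the 1-df chi-square distribution. This statistic is
  hand-rolled rather than delegated so the floor semantics are exactly as
  stated; the tail probability comes from scipy.
- **Cornfield confidence interval**: each bound is the odds ratio psi at
  which a continuity-corrected chi statistic on the table *refitted to its
  margins* at OR = psi equals the normal critical value squared. The fitted
  exposed-case cell solves the margin-preserving quadratic (Brent's method,
  tolerance 1e-12); the statistic is (|a − a*| − 0.5)² Σ(1/cell); the bounds
  are found by Brent root-finding between the point estimate and an expanding
  bracket (tolerance 1e-6, 200 iterations). The continuity-corrected variant
  was chosen because it reproduces classical epidemiological software output
  to ~2 decimal places on the reference tables; without the correction the
  bounds shift at the second decimal. On Haldane-adjusted zero-cell tables
  whose adjusted cell touches a margin, the corresponding limit is reported
  as 0 or infinity — the corrected statistic genuinely never reaches the
  critical value in that direction.
- **Reporting**: p-values are rendered to two significant figures in reports;
  full precision is kept internally. No multiple-testing adjustment is
  applied (none is standard for a single prespecified risk haplotype); the
  number of exposures tested is carried in the report so users can adjust.
- **Ambiguously phased dogs** are excluded from haplotype-level tables by
  default; allele-level tables use raw genotypes and need no phasing.
- Subgroup filters (diagnostic-grade sets, relatedness sets, age thresholds)
  are declarative and composable; the age comparison is strictly greater
  than, and subjects with missing age never pass an age filter.

## The bundled reference cohort

The statistics layer is anchored by a 212-dog cohort reconstructed from the
published group-level counts of a Hungarian Vizsla polymyositis study: 29
cases (13 definite / 4 probable / 12 possible) and 183 graded controls
(93 first-degree, 44 second-degree, 46 unrelated), with eleven three-locus
haplotypes at the published per-group chromosome counts and the published
risk-haplotype dose splits. Haplotype pairs are encoded directly (typing and
phasing are exercised by simulation instead), cleanly separating regression
tests of the statistics from the upstream layers.

Two details require care:

- **The published tables disagree by one chromosome.** The per-group
  haplotype table implies 25 risk chromosomes among the 46 unrelated controls
  (frequency 27.2%), while the dose table's 24/18/4 genotype split implies
  26. No single set of genotypes satisfies both, so the cohort has two
  variants: `haplotype_counts` (default; dose split 25/17/4 — matches every chromosome
  count and the 8.7% control homozygote frequency) and `dose_counts` (24/18/4 —
  matches the dose odds ratios 5 and 15 exactly). Each analysis is validated
  against the variant its source table supports.
- **The four rare haplotypes** (7 chromosomes, unrelated controls only) are
  unnamed in the published counts; synthetic stand-in allele triples are
  used, chosen so the toy library decomposes into 8 DRB1 / 7 DQA1 / 8 DQB1
  distinct alleles.

Within-group pairing of non-risk chromosomes into dogs is not published;
chromosomes are paired greedily by descending frequency (maximal
heterozygosity), which is deterministic and preserves every chromosome-level
statistic (pairing only affects dog-level quantities of non-risk haplotypes,
none of which are reported). Ages are assigned so that exactly 17 unrelated
controls are older than 8 years carrying 10 risk chromosomes, reproducing the
age-restricted comparison; case onset ages average 3.28 y (homozygotes) and
2.83 y (others) within the reported 0.5–8 y range.

## Synthetic cohort generator

The generator emulates the study conditions so that typing, phasing and
association can be tested end-to-end with known truth:

- **Founders** are drawn under Hardy–Weinberg on haplotypes from the
  11-haplotype pool at the all-controls frequencies (the study conditions);
  there is no recombination within the block and no genotyping error.
- **Disease model**: logistic odds on risk-copy number —
  odds(1 copy) = or_het · odds(0), odds(2) = or_hom · odds(0), with defaults
  or_het = 5, or_hom = 15 matching the dose analysis. The baseline penetrance
  f0 is a free parameter (a case-control design cannot identify prevalence);
  the default 0.05 yields a population prevalence of a few percent and makes
  ascertainment of 29 cases cheap.
- **Families**: three-generation nuclear families (four grandparent founders,
  two parents, a litter, plus a paternal half-sib litter) with Mendelian
  transmission. Affected offspring become cases until the target is reached;
  unaffected parents/siblings fill the first-degree group, unaffected
  grandparents/half-sibs the second-degree group, independent unaffected
  founders the unrelated controls. Relatives' affection is drawn under the
  same model, so control groups are conditioned on being unaffected — this is
  what produces the relatedness frequency gradient under ascertainment.
- **Ages**: case onset log-normal with median 2.9 y (sigma 0.55) truncated to
  [0.5, 8]; control ages uniform on [0.58, 13.83]. These match the reported
  ranges descriptively; the true distributions are not recoverable.
- Group sizes default to 29/93/44/46 and diagnostic grades to 13:4:12.
- A flat `simulate_case_control` sampler (ascertained founders, no families)
  is provided for parameter-recovery experiments at large n, where family
  structure is irrelevant.
- All randomness flows through one `numpy` generator; identical seeds give
  byte-identical cohorts.

What the generator does **not** emulate — and therefore what passing tests do
not show about real data: breed inbreeding (founders are drawn independently;
real breed cohorts violate Hardy–Weinberg toward homozygote excess),
population structure, typing failures and sequencing error, recombination,
and any environmental or polygenic disease component. Phasing performance on
simulated cohorts (typically 100% at the reference design size) is therefore
an upper bound: the one-hot toy library makes typing unambiguous by
construction, and HW founders provide abundant homozygote seeds.

## Verification summary

The test suite checks, among others: the IUPAC superposition table against a
literally transcribed published code table; allele-pair resolution against
exhaustive pair enumeration on random libraries (hypothesis, derandomized);
phasing against the brute-force oracle on 500 random cohorts; the ten
published regression statistics at printed precision on the reference cohort;
the five published Cornfield intervals within 10% per bound; dose-OR CI
coverage of the generating values in >= 90 of 100 seeded runs at n = 2000;
and the full 212-dog round trip (every resolved call contains the true pair,
every phased pair reconstructs its genotype). Problem sizes (500 oracle
cohorts, 100 recovery runs of 2000 dogs) were chosen to give stable rates
while keeping the default suite around ten seconds.
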