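# Methods

## Problem and scope

Given jointly genotyped father–mother–child exome trios, the package
identifies candidate germline de novo mutations (DNMs) as Mendelian
violations, filters them on genotype quality, depth and allele balance,
and estimates the mutation rate per position per generation (PPPG). The
denominator of that rate is not a raw site count: each called site
contributes the probability that a DNM arising there *would have been
observed* given the trio's actual read evidence, so low-coverage or
ambiguous sites shrink the denominator instead of silently deflating the
rate. Descriptive layers (mutation spectrum, chromosome distribution,
genomic-context regressions, predictor vote aggregation) operate on the
passing call set.

## Candidate detection and filters

Three trio genotype configurations count as candidates: child Het with
both parents HomR; child Het with both parents HomA (a back-mutation of
a population allele, reported under its own configuration label); and,
for indels only, child HomR with both parents HomA ("reversible" indel).
All other 24 genotype triples are consistent with inheritance and are
never candidates; an exhaustive enumeration test pins this down.

Filters, applied to every trio member:

* **GQ ≥ 50** (inclusive) — phred-scaled genotype quality;
* **depth > 20** (strict inequality);
* **allele balance in [0.3, 0.7]** (inclusive ends) for heterozygous
  members. For members called homozygous the balance must lie *outside*
  the band on the matching side (< 0.3 for HomR, > 0.7 for HomA): a
  nominally homozygous parent with 40% alternative reads is the
  signature of a missed heterozygote or somatic mosaicism, exactly what
  the balance filter exists to remove. Whether published trio filters
  applied the balance band to parents or only to the child is usually
  unstated; applying the consistency reading to all three members is
  this package's choice, and the thresholds are all configurable.

The first failing rule is recorded per candidate rather than a bare
fail, to support review. Trios with an extreme DNM count are flagged by
a Poisson upper-tail test (default α = 10⁻⁶) around the cohort mean —
excess apparent DNMs indicate sample mix-up or non-paternity — but they
are reported, never auto-excluded, since only an external test (e.g.
paternity analysis) can settle the cause.

## Callable-probability model

Per-sample genotype posteriors use binomial read likelihoods
L(HomR) = (1−ε)^r ε^a, L(Het) = 0.5^(r+a), L(HomA) = ε^r (1−ε)^a with a
uniform prior (a Hardy–Weinberg prior would need a population frequency
per site, which the estimator deliberately does not assume). The child
detection probabilities d_het(d) and d_homref(d) enumerate every
alt-read outcome k = 0..d, re-call the genotype by maximum likelihood,
re-derive its GQ, and sum the Binomial(d, ½) (or Binomial(d, ε)) mass of
outcomes that yield the required call *and* survive GQ/depth/balance.
They are exact finite sums, checked against an independent brute-force
enumeration to 10⁻¹² for every depth ≤ 60. A site where any member fails
the depth filter contributes P_ji = 0, reconciling "callable sites
regardless of depth" with a coverage-aware probability: such sites are
enumerated but add nothing.

The SNV probability sums the two parental configurations under which a
new child allele is detectable; the indel probability covers only the
reversible configuration, which is also the only configuration counted
in the indel-rate numerator. Heterozygous-child indel candidates are
detected and reported but enter neither rate, because the indel formula
is defined on the reversible configuration alone; this asymmetry is the
package's documented reading. p_snv is accumulated over
single-nucleotide sites and p_indel over indel sites.

## Rate estimate and confidence interval

rate = Σnᵢ / (2ΣΣP_ji). The CI treats the rate as a binomial proportion
with x = Σnᵢ successes in N = round(2ΣΣP) trials and inverts the score
test (Wilson). Wilson was adopted over Wald and Clopper–Pearson because
only the score interval reproduces published trio-study bounds when fed
the printed event counts and point estimates (the test suite
demonstrates the discrimination explicitly); rounding N is negligible at
N ~ 10⁴–10⁹. Simulation (100 cohorts of 20 trios × 10⁵ sites, μ = 10⁻⁴,
exact genotypes) shows mean relative bias around −1% and empirical CI
coverage ≈ 98%.

## Synthetic cohorts

The generator emulates the study design end to end: population
alternative-allele frequencies ~ Beta(0.5, 2) (a low-frequency-skewed
site spectrum), Hardy–Weinberg parents, Mendelian transmission of one
allele per parent, and a DNM as an independent flip of each transmitted
allele with probability μ per position per haplotype — so per-cohort
counts are Binomial(2·n_sites·n_trios, μ) and the estimator's factor 2
recovers μ directly. Read evidence: depth ~ Poisson(38.5), alt reads
binomial with p = ε, ½, 1−ε by true genotype, genotypes re-called by
maximum likelihood and GQ the phred gap to the runner-up (capped at 99,
as callers emit it). Defaults: 48 trios, mean depth 38.5, ts:tv
injection weight 1.5, indel site fraction 0.03, ε = 0.01. μ = 10⁻⁴ over
5 × 10⁴ sites is a deliberate desk-scale regime chosen once so a default
run yields a few hundred events — a whole-exome-realistic μ ~ 10⁻⁸
would require ~10⁷ callable sites per trio to see any event, and the
estimator's properties do not depend on μ's magnitude.

Context features are random interval unions (open chromatin, CpG,
H3K27ac/H3K4me1/H3K4me3) at configurable genome fractions, a
conservation score drawn so a configured fraction exceeds the >12
binarisation threshold, and an expression-specificity flag; per-feature
multipliers scale the local μ multiplicatively, giving known enrichment
for recovery tests. An optional paternal-age slope scales μ per trio
exponentially in (father_age − 32). A `perfect_calls` mode replaces the
read model with fixed-depth error-free evidence to isolate the estimator
from genotyping noise; a mosaic mode injects low-allele-balance
heterozygous miscalls to exercise the balance filter.

What the generator does **not** model: linkage disequilibrium,
recombination, sequence context around sites, mapping artifacts,
ploidy of sex chromosomes (all chromosomes are treated as autosomes),
and read-level data. Passing tests therefore certify the statistical
machinery — detection logic, probability model, estimator calibration —
not robustness to alignment or calling artifacts in real exomes.

## Context and impact layers

Stratified rates restrict both numerator and denominator of the PPPG
formula to sites with a given binary feature value, per trio; strata
with zero denominator are excluded. Single-predictor context models are
ordinary least squares of per-trio DNM rate on per-trio counts of
DNM positions carrying the feature (the only per-trio-observable
reading of "number of positions with each parameter"); slope, SE,
two-sided t-test and R² are reported and verified against the
closed-form normal equations. A score of exactly 12 is non-conserved,
the binarisation being defined by strict inequalities. Parental-age
association is a Pearson correlation of per-trio counts against each
parent's age.

Pathogenicity aggregation counts damaging/probably-damaging calls from
ten categorical predictors; `at_least_6` requires ≥ 6 votes,
`at_least_half` requires ≥ ⌈informative/2⌉ where predictors with no
call are excluded — how missing predictions were handled in published
rules is typically unstated, and excluding them is the conservative
choice recorded here. A conservation score can optionally join as an
eleventh binary vote (> 2), off by default because it is not a
damaging/tolerated classifier.

## Numerical choices and degenerate inputs

* Genotype likelihoods are computed in log10 space; the binomial
  coefficient cancels from posteriors.
* Allele balance is undefined (and not judged) when a member has no
  allele-specific reads; a record with AD exceeding DP trusts AD.
* Ts/Tv is reported as infinite when transversions are absent; Pearson
  correlations of constant vectors are reported as (0, 1) rather than
  NaN so downstream tables stay numeric.
* Concordance keys trim shared trailing bases of ref/alt so
  representation differences between callers cannot hide a match.
* Multiallelic VCF records are decomposed per alternative allele; a
  genotype allele that is neither reference nor the current alternative
  counts as reference-like. Sites with any missing trio genotype are
  excluded from both detection and the callable denominator.
* All simulation draws come from one `numpy` Generator seeded from the
  config, making outputs byte-reproducible; the CLI manifest records
  seeds and effective thresholds.

## Known limitations

The parent-side filter pass probability is not folded into P_ji (only
the child's is), which contributes a small downward bias visible in the
~−1% simulation result; at published depths (~38×) parental filter
failures are rare enough that the simplification is immaterial.
Candidate detection operates on called genotypes, not joint trio
likelihoods, so it inherits the caller's errors. The regression layer
fits single predictors only — features correlate with each other, and
no multivariable model is attempted.
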