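# dnmkit

Trio-exome **de novo mutation (DNM)** analysis: Mendelian-violation
candidate detection with conservative quality filters, callable-site
probability modelling, per-position-per-generation (PPPG) mutation-rate
estimation with Wilson confidence intervals, mutation-spectrum and
genomic-context summaries, and multi-predictor pathogenicity vote
aggregation — plus a synthetic trio-cohort generator with known ground
truth so the whole pipeline is testable without access to protected
human data.

It is written for statistical geneticists who have jointly genotyped
father–mother–child exome trios (multi-sample VCF with GT/DP/AD/GQ) and
want a germline mutation-rate estimate whose denominator honestly
reflects where a DNM *could* have been seen.

## The model

A candidate DNM is a trio genotype configuration impossible under
inheritance: a heterozygous child with both parents homozygous reference,
a heterozygous child with both parents homozygous alternative, or — for
indels — a homozygous-reference child with both parents homozygous
alternative (a "reversible" indel, the child reverting to the reference).
Candidates must pass three filters in **every** trio member: genotype
quality GQ ≥ 50, read depth > 20 (strict), and allele balance within
[0.3, 0.7] for heterozygotes (outside it, on the matching side, for
homozygotes).

The rate estimator is

    rate_PPPG = Σᵢ nᵢ / (2 · Σᵢ Σⱼ P_ji)

with `nᵢ` the passing DNMs of trio *i* and `P_ji` the probability that a
DNM arising at callable site *j* in trio *i* would have been observed.
For a single-nucleotide site

    P_ji = P(M=HomR)·P(F=HomR)·d_het(C) + P(M=HomA)·P(F=HomA)·d_het(C)

and for an indel site `P_ji = P(M=HomA)·P(F=HomA)·d_homref(C)`, where
parental genotype probabilities are posteriors under a binomial read
model with per-read error ε (default 0.01) and `d_het`/`d_homref` are the
probabilities that the child's reads at its observed depth yield the
required call *and* survive the filters. The factor 2 converts positions
into transmitted haplotype-positions. 95% CIs are Wilson score intervals
on `(Σnᵢ, round(2ΣΣP))` — the interval that remains well behaved at the
~10⁻⁸ proportions mutation rates live at.

## Worked example

```bash
cat > config.yaml <<EOF
simulate:
  n_trios: 6
  n_sites: 4000
  mu: 0.001
EOF
dnmkit all --config config.yaml --seed 7 --out-dir run
cat run/rates.tsv run/spectrum.tsv
```

prints (seed 7):

```
variant_class  n_mutations  denominator  rate        ci_low       ci_high      n_trios
snv            20           26503.4      0.00075462  0.000488582  0.00116539   6
indel          0            43.888       0           0            0.0802956    6
metric             value
n_pass             22
per_person_mean    3.6666666666666665
tstv               1.5
r_gene_density     -0.10636229321116654
p_gene_density     0.6375673521603508
```

Read: 20 passing single-nucleotide DNMs over a callable denominator of
~26,500 haplotype-positions give a rate of 7.5 × 10⁻⁴ per position per
generation whose Wilson CI [4.9 × 10⁻⁴, 1.2 × 10⁻³] covers the simulated
truth μ = 10⁻³; the transition:transversion ratio of the call set is 1.5
(the generator's injection weight); DNM counts show no significant
correlation with gene density across chromosomes (p = 0.64). The output
directory also contains per-candidate reports, callable-probability sums
per trio, per-chromosome and substitution tables, context regressions,
parental-age correlations and the likely-pathogenic selection, plus a
`manifest.json` recording seeds and effective thresholds. Identical
config + seed reproduces the directory byte for byte.

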