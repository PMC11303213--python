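# carrierprev

Carrier- and affected-rate estimation for rare recessive disease from
population cohort data, with ancestry-aware ACMG frequency evidence.

Estimating how common a rare autosomal-recessive disease *could* be is hard to
do by counting patients — the affected are too few. A population-genetics
shortcut is to count the **carriers** instead: intersect the variants observed
in a healthy reference cohort (a 1000 Genomes-style phased VCF plus its
two-level sample panel) with a catalog of variants asserted to be
disease-causing (an HGMD-style export), measure the pathogenic allele
frequency, and convert it to expected carrier and affected rates under
Hardy-Weinberg equilibrium. `carrierprev` implements that pipeline end to end
for a single gene region, with the CTNS locus (cystinosis, chromosome 17p13,
GRCh37) as its worked default.

The catch, and the reason this package exists as more than a calculator: allele
frequencies differ across ancestral groups, and the ACMG **BA1** rule (allele
frequency above 5% in a general continental population is stand-alone benign
evidence) can reclassify a catalogued pathogenic allele in one ancestry only.
Whether such an allele belongs in the prevalence estimate is a judgement call —
for variants with variable expressivity, apparent "healthy carriers" may simply
be under-phenotyped. `carrierprev` therefore never deletes a variant
automatically: frequency evidence becomes flags, and the prevalence engine
computes every inclusion/exclusion scenario side by side.

Intended users: statistical/medical geneticists and bioinformaticians doing
gene-level carrier screening or prevalence estimation from reference cohorts.

## Model

For included pathogenic variants *i* with alternate allele counts
AC<sub>i</sub> over a shared allele number AN (non-missing allele slots), the
combined pathogenic allele frequency pools all alleles at one locus
(full allelic heterogeneity — any two pathogenic alleles in trans cause
disease):

    q = Σᵢ ACᵢ / AN,   p = 1 − q

Under Hardy-Weinberg equilibrium:

    carrier rate  = 2pq        affected rate = q²

Two carrier-rate conventions are always reported, because they genuinely
differ: the HWE rate 2pq, and the **observed** rate (distinct carrier
individuals / cohort size; a homozygote is one carrier, a person carrying two
variants counts once). All arithmetic is exact rational (`fractions.Fraction`);
"1 in X" values are the reciprocal rounded half-up, and percentages can be
formatted by half-up rounding or truncation (published tables mix both).

Frequency evidence: BA1 triggers iff af > 5% (strict) in **at least one**
ancestry group — evaluated per group, never pooled, since an allele common in
one ancestry would never trigger on the pooled frequency. Optional BS1 and PM2
thresholds are supported but disabled by default.

## Worked example

```python
from carrierprev import FixtureSpec, generate_fixture, RunConfig, run_pipeline

paths = generate_fixture(FixtureSpec(seed=0), "fixture")
summary = run_pipeline(RunConfig(
    vcf=paths.cohort_vcf, panel=paths.panel, catalog=paths.catalog,
    freq_table=paths.external_freq, policy="all", out_dir="out",
))
```

or, from the shell, `carrierprev simulate --out fixture --seed 0` followed by
`carrierprev run --vcf fixture/cohort.vcf --panel fixture/samples.panel
--catalog fixture/catalog.tsv --freq-table fixture/external_frequencies.tsv
--out out`. Running `python examples/05_prevalence_scenarios.py` prints:

```
scenario 'all': q = 3/182 (1.64% truncated / 1.65% rounded)
    carrier  : 1 in 30 observed, 1 in 31 by HWE 2pq
    affected : 1 in 3680 (q^2)
scenario 'acmg_filtered': q = 1/2184 (0.04% truncated / 0.05% rounded)
    carrier  : 1 in 1092 observed, 1 in 1093 by HWE 2pq
    affected : 1 in 4769856 (q^2)
```

Reading: with both catalog variants included, the pooled pathogenic allele
frequency is 36/2184 (= 3/182, 1.64%), one person in 30 in the cohort carries a
pathogenic allele, and one birth in ~3,680 is expected to inherit two. The
`acmg_filtered` policy drops the variant whose African-ancestry frequency
(6.26%) exceeds the BA1 threshold despite its pathogenic assertion — the
reconciliation report flags it `conflict_benign_vs_pathogenic` — leaving
q = 1/2184, a carrier rate of 1 in 1,093 (2pq) and an affected rate of exactly
1 in 2184² = 4,769,856. The three-orders-of-magnitude spread between scenarios
is the point: classification choices dominate the estimate.

The `examples/` scripts walk each capability (fixture simulation, catalog
intersection, stratified frequencies, frequency evidence, prevalence
scenarios) with commentary; `carrierprev run` writes four TSV reports plus a
JSON run summary with input hashes and the full configuration.

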