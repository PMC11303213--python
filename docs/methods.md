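# Methods

## Problem and model

`carrierprev` estimates the genetic prevalence of a rare autosomal-recessive
disease from a healthy reference cohort. The chain of reasoning: variants
observed in the cohort are intersected with a catalog of asserted
disease-causing variants; the included pathogenic alleles are pooled into a
single combined allele frequency q = (Σ AC) / AN in a chosen population
stratum; Hardy-Weinberg equilibrium converts q into a carrier rate 2pq and an
affected rate q² (p = 1 − q).

Assumptions this encodes, in decreasing order of innocence:

- **Random mating, no inbreeding correction.** Founder effects and
  consanguinity raise the homozygote rate above q²; no F-coefficient
  adjustment is applied. Estimates are population-average figures.
- **Full allelic heterogeneity at one locus.** Any two included pathogenic
  alleles in trans are assumed to cause disease, so the affected rate is
  (Σqᵢ)² rather than Σqᵢ². For a small q the difference is second-order, but
  it is a modelling choice and is labelled in the reports.
- **The catalog is the definition of "pathogenic".** The pipeline measures the
  consequences of that definition (including its ancestry-dependent fragility)
  rather than adjudicating it.

Two carrier-rate conventions coexist and are always reported side by side:

- *HWE*: 2pq, a function of allele frequency alone;
- *observed*: distinct carrier individuals / cohort size, where a homozygote
  is one carrier and a person carrying two distinct variants counts once.

For 36 carriers of 36 alleles among 1092 people these give 1 in 30.33 and
1 in 30.84 (reciprocal scale), and for a single allele 1 in 1092 vs 1 in
1092.5; published figures mix the conventions, so each report cell carries its
label and no single convention is silently preferred.

## Exact arithmetic and rounding

q, 2pq, q² and all reciprocals are `fractions.Fraction`; floats appear only at
formatting. This keeps identities exact (an affected rate of (1/2184)² is
exactly 1/4,769,856, not a float neighbour) and makes invariants testable with
`==`. "1 in X" figures round the exact reciprocal half-up (1092.5002 → 1093;
3680.44 → 3680). Percentages are formatted by `decimal` with either half-up
rounding or truncation; both styles appear in the reports because published
tables use both (1/2184 is 0.05% rounded but 0.04% truncated), and the exact
fraction is printed alongside as the source of truth.

## Variant identity and VCF handling

The join key throughout is the normalized (chrom, pos, ref, alt) tuple; rsIDs
are carried for reporting only, since dbSNP identifiers drift across builds.
Normalization trims the shared allele suffix, then the shared prefix, keeping
at least one base each and adjusting the position; with a reference context it
also left-aligns indels by the standard shift-left procedure. Normalization is
idempotent (property-tested).

Cohort VCFs are parsed with cyvcf2 (htslib). Multiallelic records are
decomposed into one biallelic record per alternate allele; in the record for
alt *k*, a sample allele equal to *k* recodes to 1, reference to 0, and any
*other* alt to **missing** — an other-alt slot carries no information about
this alt and must not inflate the reference count. Genotype phase is parsed
and discarded (no downstream count uses it). Missing allele slots are retained
and excluded from AN. Coordinates are 1-based (GRCh37, recorded in all
outputs); region arguments are half-open [start, end) so adjacent subsets
tile. A lightweight structural pre-scan supplies line-numbered parse errors,
which htslib does not.

## Frequency evidence and reconciliation

BA1 triggers iff af > ba1 (default 5%, strict: "more than 5%" excludes
equality, and the boundary is unit-tested at af = 5% and 5% + 1/10¹²) in at
least one ancestry group. The evaluation is deliberately per-group: the pooled
frequency of an allele common in a single ancestry may sit far below the
threshold, and the per-group calls record that the classification differs
across ancestries. Filtering-allele-frequency (popmax CI) refinements are out
of scope; raw frequencies are compared to thresholds. BS1 and PM2 are
implemented but disabled by default — their values are guideline- and
gene-specific and no default is defensible. PM2 requires af ≤ pm2_max in
*every* group (absence/rarity across populations).

Reconciliation against the catalog emits a closed verdict vocabulary:

- `conflict_benign_vs_pathogenic`: benign-direction frequency call vs
  pathogenic-direction assertion — the flag the whole pipeline pivots on;
- `frequency_silent`: no usable frequency signal (no code triggered, or PM2
  support against a non-pathogenic assertion, which is supporting evidence,
  not a classification);
- `concordant`: everything else, including a benign-direction call on a VUS
  assertion (frequency refines a VUS; calling that a conflict would overstate
  it).

Conflicted variants are never dropped automatically. The prevalence engine
takes explicit policies: `all`, `acmg_filtered` (drop conflicted),
`leave_one_out`, or an explicit key list, and recomputes the observed carrier
rate per scenario from the carriers of the included variants only.

## Synthetic data generator

Real inputs of this kind (phased reference-cohort VCFs, licensed pathogenic
catalogs) are bulky or access-restricted, so `carrierprev.simulate` generates
seeded fixtures with the statistical structure the pipeline must handle:

- **Cohort**: 1092 diploid samples in the 14 subpopulations / 4
  superpopulations of the 1000 Genomes Phase 1 panel composition (ASW 61,
  LWK 97, YRI 88; CLM 60, MXL 66, PUR 55; CHB 97, CHS 100, JPT 89; CEU 85,
  FIN 93, GBR 89, IBS 14, TSI 98) — the least arbitrary choice of plausible
  sizes. 444 unique variants in the CTNS region (chr17:3,539,771–3,564,700,
  GRCh37).
- **Overlap variants** (defaults): chr17:3550800 G>A (c.124G>A, p.Val42Ile,
  atypical disease) in 35 heterozygotes, placed by weighted sampling with 0.9
  of the mass on African-ancestry samples so the per-stratum reports exercise
  the per-group BA1 logic (AFR frequency lands near the external table's
  6.26%); chr17:3559792 T>C (c.473T>C, p.Leu158Pro, severe infantile disease)
  in 1 heterozygote placed uniformly. The subpopulation-level placement of
  carriers is one random draw consistent with the pooled counts — only pooled
  counts are constrained — and the draw is recorded in
  `fixture_metadata.json`.
- **Background variants**: 442 SNVs at uniform positions (excluding overlap
  positions), ref/alt uniform over ACGT pairs, per-site allele frequency
  log-uniform between 1/(2N) and 2% with at least one observed copy — a
  rare-variant-dominated site-frequency shape sufficient for every downstream
  count; no linkage disequilibrium, relatedness, phasing structure or
  sequencing error is simulated.
- **Catalog**: the overlap entries plus 73 decoys at positions absent from the
  cohort, mostly `pathogenic` with some `likely_pathogenic`.
- **External table**: only the four published per-ancestry frequencies of the
  common allele (AFR 6.26%, NFE 0.006%, FIN 0%, Asian 0.002%); the rare allele
  has no external rows, so the pipeline's fallback path (cohort
  superpopulation frequencies → all below threshold → `frequency_silent`) is
  exercised by the default fixture itself.

Determinism: everything derives from one `numpy` Generator seeded from the
spec (the catalog decoys from an offset stream so cohort bytes do not depend
on catalog parameters); identical spec + seed gives byte-identical files,
which is hash-tested.

What passing on this fixture does **not** show: robustness to real-data
messiness (multi-sample ploidy anomalies, symbolic alleles, panel/cohort ID
mismatches beyond the tested error paths) or to linkage between catalog
variants; the fixture's integer counts are constructed, so fixture tests
validate the computation, not the biology.

## Pipeline, reports, problem sizes

`run_pipeline` executes read → intersect → frequencies → evidence → reconcile
→ scenarios → report from one declarative config (JSON file or flags; flags
override keys one-to-one). Reports are TSV plus a JSON run summary carrying
the tool version, SHA-256 of every input, the full config and the genome
build; no timestamps, so identical config + inputs reproduce identical bytes.
Stage failures are re-raised with the stage name and surface as a nonzero CLI
exit.

Default problem sizes everywhere (tests, examples, acceptance script) are the
study-scale fixture — 1092 samples × 444 variants — which runs in seconds;
property tests use 8–20-sample cohorts where an exhaustive per-sample oracle
is feasible. Thresholds and generator parameters are fixed by the study
conditions described above and are not tuning knobs.

## Known limitations

- No confidence intervals on q or the rates (binomial/bootstrap CIs are the
  natural extension).
- No per-stratum Hardy-Weinberg disequilibrium testing.
- No structural variants, symbolic alleles, breakends, or ploidy ≠ 2.
- HGVS c./p. strings are opaque labels; no transcript-level validation.
- The chrom-prefix unifier handles "17"/"chr17" dialects only; exotic contig
  naming passes through as-is.
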