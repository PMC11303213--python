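"""Generate the default synthetic study fixture.

Writes a seeded cohort VCF (1092 diploid samples, 444 unique variants in
the CTNS region of chr17, GRCh37), a 1000 Genomes-style sample panel,
a 75-entry pathogenic-variant catalog TSV, and a gnomAD-style external
ancestry-frequency table.  Identical seeds give byte-identical files.
"""

import tempfile

from carrierprev import FixtureSpec, generate_fixture, read_cohort_vcf, read_panel

out = tempfile.mkdtemp(prefix="carrierprev_fixture_")
paths = generate_fixture(FixtureSpec(seed=0), out)

cohort = read_cohort_vcf(paths.cohort_vcf)
panel = read_panel(paths.panel)
print(f"cohort VCF     : {paths.cohort_vcf}")
print(f"sample panel   : {paths.panel}")
print(f"catalog TSV    : {paths.catalog}")
print(f"external freqs : {paths.external_freq}")
print(f"{cohort.n_samples} samples, {cohort.n_variants} unique variants, "
      f"{len(panel.subpopulations)} subpopulations in "
      f"{len(panel.superpopulations)} superpopulations")
# The counts mirror the study conditions: a healthy reference cohort in
# which every pipeline stage can be exercised without restricted data.
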