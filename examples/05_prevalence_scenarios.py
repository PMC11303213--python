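"""Hardy-Weinberg carrier and affected rates under inclusion scenarios.

The combined pathogenic allele frequency q pools every included allele
at one locus (full allelic heterogeneity), so the affected rate is q²
and the HWE carrier rate 2pq.  The observed carrier rate (distinct
carriers / cohort size) is reported alongside, because the two
conventions genuinely differ and neither dominates.
"""

import tempfile
from fractions import Fraction

from carrierprev import (
    FixtureSpec,
    RunConfig,
    format_percent,
    generate_fixture,
    run_pipeline,
)

workdir = tempfile.mkdtemp()
paths = generate_fixture(FixtureSpec(seed=0), workdir)

for policy in ("all", "acmg_filtered"):
    summary = run_pipeline(RunConfig(
        vcf=paths.cohort_vcf, panel=paths.panel, catalog=paths.catalog,
        freq_table=paths.external_freq, policy=policy,
        out_dir=f"{workdir}/out_{policy}", log_level="WARNING",
    ))
    (sc,) = summary["scenarios"]
    q = Fraction(sc["q"]["exact"])
    print(f"scenario '{policy}': q = {sc['q']['exact']} "
          f"({format_percent(q, 'truncate')}% truncated / "
          f"{format_percent(q, 'round')}% rounded)")
    print(f"    carrier  : 1 in {sc['one_in_carrier_observed']} observed, "
          f"1 in {sc['one_in_carrier_hwe']} by HWE 2pq")
    print(f"    affected : 1 in {sc['one_in_affected']} (q^2)")
# Including both variants: q=36/2184, carriers 1 in 30 (observed),
# affected 1 in 3,680.  Excluding the ancestry-conflicted variant:
# q=1/2184, carriers 1 in 1,093 (HWE), affected 1 in 4,769,856 = 2184².
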