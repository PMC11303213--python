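"""ACMG frequency evidence per ancestry group, reconciled with the catalog.

BA1 (stand-alone benign) triggers when the allele frequency is strictly
above 5% in at least one continental ancestry group.  Evaluating per
group — not on the pooled frequency — is what exposes the dilemma: an
allele common in one ancestry only would never trigger on pooled data.
Nothing is deleted automatically; conflicts become flags that the
prevalence scenarios consume as explicit inclusion policies.
"""

import tempfile

from carrierprev import (
    EvidenceThresholds,
    FixtureSpec,
    assign_evidence,
    generate_fixture,
    intersect,
    load_catalog,
    read_cohort_vcf,
    read_external_frequencies,
    reconcile,
)

paths = generate_fixture(FixtureSpec(seed=0), tempfile.mkdtemp())
cohort = read_cohort_vcf(paths.cohort_vcf)
result = intersect(cohort, load_catalog(paths.catalog))
external = read_external_frequencies(paths.external_freq)
thresholds = EvidenceThresholds()  # BA1 > 5%, strict

for cv, _ in result.matched:
    freqs = external.freqs_for(cv.cdna_name)
    assignment = assign_evidence(freqs, thresholds, key=cv.key)
    verdict = reconcile(assignment, cv)
    print(f"{cv.key} ({cv.cdna_name}) asserted={cv.asserted_classification.value}")
    for group, af in sorted(freqs.items()):
        print(f"    {group:>6}: af={float(af):.5%}  -> {assignment.per_group_calls[group]}")
    print(f"    triggered={sorted(assignment.triggered) or '-'}  verdict={verdict.verdict}")
# The common allele is benign by frequency in the African group alone,
# conflicting with its pathogenic assertion; the rare allele's
# frequencies are silent (no code triggers either way).
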