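"""ACMG frequency-based evidence codes and catalog reconciliation.

Only the allele-frequency criteria are implemented: BA1 (stand-alone
benign, allele frequency strictly above 5% in at least one general
continental ancestry group), optional BS1 (strong benign) and optional
PM2 (supporting pathogenic via absence/rarity across all groups).  The
full 28-criterion combining framework is out of scope.

BA1 is evaluated per ancestry group, not on the pooled frequency: a
variant common in one ancestry but rare elsewhere — the interesting case
for equity-aware curation — would never trigger on a pooled cohort
frequency.  Nothing here deletes a variant: reconciliation produces
flags, and prevalence scenarios consume explicit inclusion policies,
because automatic exclusion of an ancestry-specific allele may itself be
confounded by unequal access to phenotyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .catalog import CatalogVariant, Classification
from .errors import FrequencyRangeError, UsageError
from .variants import VariantKey

logger = logging.getLogger(__name__)

Number = Fraction | float | int


@dataclass(frozen=True)
class EvidenceThresholds:
    """Frequency thresholds for the benign/pathogenic evidence codes.

    ba1: stand-alone benign threshold, strict ">" (default 0.05, i.e.
    "more than 5%").  bs1: optional strong-benign threshold, must be
    below ba1.  pm2_max: optional rarity ceiling at-or-below which (in
    every group) absence-based pathogenic support applies; disabled by
    default since defaults for them are guideline- and gene-specific.
    """

    ba1: Fraction = Fraction(5, 100)
    bs1: Fraction | None = None
    pm2_max: Fraction | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ba1 <= 1:
            raise UsageError(f"ba1 must be in (0, 1], got {self.ba1}")
        if self.bs1 is not None and not self.bs1 < self.ba1:
            raise UsageError("bs1 must be below ba1")
        if self.pm2_max is not None:
            ceiling = self.bs1 if self.bs1 is not None else self.ba1
            if not self.pm2_max < ceiling:
                raise UsageError("pm2_max must be below bs1 (and ba1)")


@dataclass
class EvidenceAssignment:
    """Outcome of frequency-evidence evaluation for one variant."""

    key: VariantKey | None
    triggered: set[str]
    triggering_strata: dict[str, list[tuple[str, Fraction]]]
    frequency_classification: str  # benign | likely_benign | no_frequency_call | supports_pathogenic
    per_group_calls: dict[str, str]
    conflict: bool = False


def _as_fraction(value: Number, group: str) -> Fraction:
    frac = value if isinstance(value, Fraction) else Fraction(value)
    if not 0 <= frac <= 1:
        raise FrequencyRangeError(f"af {value} for group {group!r} outside [0, 1]")
    return frac


def assign_evidence(
    freqs: Mapping[str, Number],
    thresholds: EvidenceThresholds | None = None,
    key: VariantKey | None = None,
) -> EvidenceAssignment:
    """Assign frequency-evidence codes from per-ancestry allele frequencies.

    BA1 triggers iff af > ba1 in at least one group (strict inequality:
    a frequency of exactly 5% is not "more than 5%").  BS1 likewise with
    its own threshold.  PM2 requires af <= pm2_max in *every* group.
    ``per_group_calls`` records the would-be call from each group alone,
    which is how a call that differs across ancestries becomes visible.
    Deterministic under any iteration order of ``freqs``.
    """
    th = thresholds or EvidenceThresholds()
    groups = {g: _as_fraction(v, g) for g, v in sorted(freqs.items())}
    if not groups:
        logger.warning("empty frequency map%s: no frequency call", f" for {key}" if key else "")
        return EvidenceAssignment(
            key=key, triggered=set(), triggering_strata={},
            frequency_classification="no_frequency_call", per_group_calls={},
        )

    def group_call(af: Fraction) -> str:
        if af > th.ba1:
            return "benign"
        if th.bs1 is not None and af > th.bs1:
            return "likely_benign"
        if th.pm2_max is not None and af <= th.pm2_max:
            return "supports_pathogenic"
        return "no_frequency_call"

    per_group = {g: group_call(af) for g, af in groups.items()}
    triggered: set[str] = set()
    strata: dict[str, list[tuple[str, Fraction]]] = {}
    ba1_hits = [(g, af) for g, af in groups.items() if af > th.ba1]
    if ba1_hits:
        triggered.add("BA1")
        strata["BA1"] = ba1_hits
    if th.bs1 is not None:
        bs1_hits = [(g, af) for g, af in groups.items() if th.bs1 < af <= th.ba1]
        if bs1_hits:
            triggered.add("BS1")
            strata["BS1"] = bs1_hits
    if th.pm2_max is not None and all(af <= th.pm2_max for af in groups.values()):
        triggered.add("PM2")
        strata["PM2"] = list(groups.items())

    if "BA1" in triggered:
        classification = "benign"
    elif "BS1" in triggered:
        classification = "likely_benign"
    elif "PM2" in triggered:
        classification = "supports_pathogenic"
    else:
        classification = "no_frequency_call"
    return EvidenceAssignment(
        key=key,
        triggered=triggered,
        triggering_strata=strata,
        frequency_classification=classification,
        per_group_calls=per_group,
    )


@dataclass(frozen=True)
class ReconciliationRecord:
    """Frequency evidence weighed against the catalog's assertion."""

    key: VariantKey
    asserted: Classification
    frequency_classification: str
    verdict: str  # concordant | conflict_benign_vs_pathogenic | frequency_silent
    triggered: tuple[str, ...]
    triggering_strata: dict[str, list[tuple[str, Fraction]]]


def reconcile(
    assignment: EvidenceAssignment,
    catalog_entry: CatalogVariant,
) -> ReconciliationRecord:
    """Compare a frequency-evidence assignment with the catalog assertion.

    Verdicts: ``conflict_benign_vs_pathogenic`` when the frequency call
    is benign-direction while the catalog asserts pathogenic-direction;
    ``frequency_silent`` when the frequency data carries no usable
    signal for the assertion; ``concordant`` otherwise.
    """
    if assignment.key is not None and assignment.key != catalog_entry.key:
        raise UsageError(
            f"key mismatch: evidence for {assignment.key}, catalog entry {catalog_entry.key}"
        )
    asserted = catalog_entry.asserted_classification
    fc = assignment.frequency_classification
    if fc in ("benign", "likely_benign"):
        verdict = (
            "conflict_benign_vs_pathogenic" if asserted.pathogenic_direction else "concordant"
        )
    elif fc == "supports_pathogenic":
        verdict = "concordant" if asserted.pathogenic_direction else "frequency_silent"
    else:
        verdict = "frequency_silent"
    conflict = verdict == "conflict_benign_vs_pathogenic"
    assignment.conflict = conflict
    return ReconciliationRecord(
        key=catalog_entry.key,
        asserted=asserted,
        frequency_classification=fc,
        verdict=verdict,
        triggered=tuple(sorted(assignment.triggered)),
        triggering_strata=assignment.triggering_strata,
    )
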