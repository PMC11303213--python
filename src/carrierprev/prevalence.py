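"""Carrier- and affected-rate estimation under Hardy-Weinberg equilibrium.

The model: pool every included pathogenic allele at a single locus into
a combined pathogenic allele frequency q = (Σ ac) / an — full allelic
heterogeneity, i.e. any two pathogenic alleles in trans cause disease.
Under random mating the carrier rate is 2pq (p = 1 − q) and the affected
rate q².  Two carrier-rate conventions exist side by side and are always
both reported:

* HWE: 2pq, derived from allele frequency alone;
* observed: distinct carrier individuals / cohort size, available when
  genotypes are.

They differ (e.g. 36 carriers among 1092 people is 1 in 30.33 observed,
while q = 36/2184 gives 2pq = 1 in 1092.5·… reciprocal scale for the
rare case) and neither dominates: each report cell is labelled.

All rates are exact :class:`fractions.Fraction` internally; floats
appear only at formatting, so quantities like an affected rate of
1/2184² survive without floating-point blur.  "One in X" renderings
round the exact reciprocal half-up to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .acmg import ReconciliationRecord
from .catalog import IntersectionResult
from .errors import UndefinedFrequencyError, UsageError
from .popfreq import AlleleFrequencyRecord
from .variants import VariantKey


class _Never:
    """Sentinel for the reciprocal of a zero rate."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "never"


NEVER = _Never()


def combined_q(
    records: Sequence[AlleleFrequencyRecord],
    stratum: str = "ALL",
) -> Fraction:
    """Combined pathogenic allele frequency (Σ ac) / an for one stratum.

    All included pathogenic alleles are treated as interchangeable at
    one locus.  Records must all belong to ``stratum`` and agree on AN.
    An empty inclusion set gives q = 0.
    """
    relevant = [r for r in records]
    if not relevant:
        return Fraction(0)
    strata = {r.stratum for r in relevant}
    if strata != {stratum}:
        raise UsageError(f"records span strata {sorted(strata)}, expected only {stratum!r}")
    ans = {r.an for r in relevant}
    if len(ans) != 1:
        raise UsageError(f"records disagree on allele number: {sorted(ans)}")
    an = ans.pop()
    if an == 0:
        raise UndefinedFrequencyError(f"allele number is 0 in stratum {stratum!r}")
    return Fraction(sum(r.ac for r in relevant), an)


def hwe_rates(q: Fraction | float) -> tuple[Fraction, Fraction]:
    """(carrier rate 2q(1−q), affected rate q²) under Hardy-Weinberg."""
    qf = q if isinstance(q, Fraction) else Fraction(q)
    if not 0 <= qf <= 1:
        raise UsageError(f"q must be in [0, 1], got {q}")
    return 2 * qf * (1 - qf), qf * qf


def observed_carrier_rate(result: IntersectionResult, cohort_size: int) -> Fraction:
    """Distinct carrier individuals / cohort size."""
    if cohort_size <= 0:
        raise UsageError("cohort size must be positive")
    n = len(result.carrier_samples)
    if n > cohort_size:
        raise UsageError(f"{n} carriers exceed cohort size {cohort_size}")
    return Fraction(n, cohort_size)


def one_in(rate: Fraction | float):
    """Reciprocal of a rate, rounded half-up to the nearest integer.

    Returns the :data:`NEVER` sentinel for a zero rate.  Use
    :func:`one_in_exact` for the unrounded reciprocal.
    """
    r = rate if isinstance(rate, Fraction) else Fraction(rate)
    if r < 0:
        raise UsageError(f"rate must be non-negative, got {rate}")
    if r == 0:
        return NEVER
    return int(math.floor(1 / r + Fraction(1, 2)))


def one_in_exact(rate: Fraction | float):
    """Exact reciprocal of a rate (Fraction), or NEVER for zero."""
    r = rate if isinstance(rate, Fraction) else Fraction(rate)
    if r == 0:
        return NEVER
    return 1 / r


@dataclass
class PrevalenceEstimate:
    """Hardy-Weinberg prevalence summary for one inclusion scenario."""

    scenario_label: str
    included_keys: list[VariantKey]
    q: Fraction
    carrier_rate_observed: Fraction | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.q <= 1:
            raise UsageError(f"q must be in [0, 1], got {self.q}")

    @property
    def p(self) -> Fraction:
        return 1 - self.q

    @property
    def carrier_rate_hwe(self) -> Fraction:
        return 2 * self.p * self.q

    @property
    def affected_rate(self) -> Fraction:
        return self.q * self.q

    @property
    def one_in_carrier_hwe(self):
        return one_in(self.carrier_rate_hwe)

    @property
    def one_in_carrier_observed(self):
        if self.carrier_rate_observed is None:
            return None
        return one_in(self.carrier_rate_observed)

    @property
    def one_in_affected(self):
        return one_in(self.affected_rate)

    def as_dict(self) -> dict:
        """JSON-friendly rendering with exact fractions alongside floats."""
        def frac(x):
            return None if x is None else {"exact": f"{x.numerator}/{x.denominator}", "float": float(x)}

        def oin(x):
            return None if x is None else ("never" if x is NEVER else x)

        return {
            "scenario": self.scenario_label,
            "included_variants": [str(k) for k in self.included_keys],
            "q": frac(self.q),
            "p": frac(self.p),
            "carrier_rate_hwe": frac(self.carrier_rate_hwe),
            "carrier_rate_observed": frac(self.carrier_rate_observed),
            "affected_rate": frac(self.affected_rate),
            "one_in_carrier_hwe": oin(self.one_in_carrier_hwe),
            "one_in_carrier_observed": oin(self.one_in_carrier_observed),
            "one_in_affected": oin(self.one_in_affected),
        }


def sensitivity_scenarios(
    records: Sequence[AlleleFrequencyRecord],
    intersection: IntersectionResult,
    reconciliations: Sequence[ReconciliationRecord] = (),
    policy: str = "all",
    explicit_keys: Sequence[VariantKey] | None = None,
    cohort_size: int | None = None,
    stratum: str = "ALL",
) -> list[PrevalenceEstimate]:
    """Prevalence estimates across variant inclusion/exclusion scenarios.

    Policies: "all" includes every intersected variant; "acmg_filtered"
    drops variants whose reconciliation verdict is
    ``conflict_benign_vs_pathogenic``; "leave_one_out" emits one
    scenario per dropped variant; "explicit" uses ``explicit_keys``.
    The observed carrier rate is recomputed per scenario from the
    carriers of the included variants when ``cohort_size`` is given.
    """
    matched_keys = intersection.matched_keys
    by_key = {r.key: r for r in records if r.stratum == stratum}
    missing = [k for k in matched_keys if k not in by_key]
    if missing:
        raise UsageError(f"no {stratum!r} frequency record for matched keys: {missing}")
    conflicted = {
        r.key for r in reconciliations if r.verdict == "conflict_benign_vs_pathogenic"
    }

    def build(label: str, keys: list[VariantKey]) -> PrevalenceEstimate:
        q = combined_q([by_key[k] for k in keys], stratum) if keys else Fraction(0)
        observed = None
        if cohort_size is not None:
            observed = Fraction(len(intersection.carriers_of(keys)), cohort_size)
        return PrevalenceEstimate(
            scenario_label=label,
            included_keys=list(keys),
            q=q,
            carrier_rate_observed=observed,
        )

    if policy == "all":
        return [build("all", matched_keys)]
    if policy == "acmg_filtered":
        kept = [k for k in matched_keys if k not in conflicted]
        return [build("acmg_filtered", kept)]
    if policy == "leave_one_out":
        return [
            build(f"without:{dropped}", [k for k in matched_keys if k != dropped])
            for dropped in matched_keys
        ]
    if policy == "explicit":
        keys = list(explicit_keys or [])
        unknown = [k for k in keys if k not in by_key]
        if unknown:
            raise UsageError(f"explicit keys not among frequency records: {unknown}")
        return [build("explicit", keys)]
    raise UsageError(
        f"unknown policy {policy!r}; expected all, acmg_filtered, leave_one_out or explicit"
    )
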