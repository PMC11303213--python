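"""Ancestry-stratified allele counts and frequencies.

Frequencies are computed per subpopulation, per superpopulation, and
pooled ("ALL").  Allele number (AN) counts non-missing allele slots, not
2N, so records stay correct under missing genotypes; on a fully-called
cohort the two coincide.  Exact fractions are the source of truth —
:func:`format_percent` supports both rounding and truncation because
published reports mix the two conventions (e.g. 36/2184 prints as 1.64%
truncated but 1.65% rounded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FrequencyRangeError, UnassignedSamplesError, UsageError
from .variants import GenotypeMatrix, SamplePanel, VariantKey

logger = logging.getLogger(__name__)

#: default mapping from external (gnomAD-style) ancestry labels to
#: 1000 Genomes-style superpopulation codes
DEFAULT_ANCESTRY_MAP: dict[str, str] = {
    "AFR": "AFR",
    "NFE": "EUR",
    "FIN": "EUR",
    "EAS": "EAS",
    "SAS": "EAS",
    "Asian": "EAS",
    "AMR": "AMR",
}


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """AC/AN/AF for one variant in one population stratum."""

    key: VariantKey
    stratum: str
    ac: int
    an: int
    n_het: int
    n_hom_alt: int
    absent: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.ac <= self.an:
            raise UsageError(f"require 0 <= ac <= an, got ac={self.ac} an={self.an}")
        if self.ac != self.n_het + 2 * self.n_hom_alt:
            raise UsageError(
                f"ac ({self.ac}) != n_het + 2*n_hom_alt "
                f"({self.n_het} + 2*{self.n_hom_alt})"
            )

    @property
    def af(self) -> Fraction | None:
        """Exact allele frequency, or None when AN = 0 (undefined)."""
        if self.an == 0:
            return None
        return Fraction(self.ac, self.an)


def stratified_frequencies(
    cohort: GenotypeMatrix,
    panel: SamplePanel,
    keys: Sequence[VariantKey],
) -> list[AlleleFrequencyRecord]:
    """Allele counts per stratum for the requested variants.

    Strata are "ALL", every superpopulation, and every subpopulation in
    the panel.  Missing allele slots are excluded from AN.  A key absent
    from the cohort yields records with ac = 0 and the stratum's full
    allele number, flagged ``absent``.
    """
    unassigned = [s for s in cohort.samples if s not in panel]
    if unassigned:
        raise UnassignedSamplesError(
            f"{len(unassigned)} cohort sample(s) missing from panel: "
            + ", ".join(unassigned[:10])
            + ("..." if len(unassigned) > 10 else "")
        )
    sample_pos = {s: j for j, s in enumerate(cohort.samples)}
    sub_to_super = panel.subpopulations
    strata: list[str] = ["ALL"] + panel.superpopulations + sorted(sub_to_super)
    stratum_idx = {
        stratum: np.array(
            [sample_pos[s] for s in panel.samples_in(stratum) if s in sample_pos],
            dtype=np.intp,
        )
        for stratum in strata
    }
    index = {k: i for i, k in enumerate(cohort.variants)}
    records: list[AlleleFrequencyRecord] = []
    for key in keys:
        i = index.get(key)
        for stratum in strata:
            idx = stratum_idx[stratum]
            if i is None:
                records.append(
                    AlleleFrequencyRecord(
                        key=key, stratum=stratum, ac=0, an=2 * len(idx),
                        n_het=0, n_hom_alt=0, absent=True,
                    )
                )
                continue
            dosage = cohort.alt_dosage(i)[idx]
            called = cohort.called_alleles(i)[idx]
            records.append(
                AlleleFrequencyRecord(
                    key=key,
                    stratum=stratum,
                    ac=int(dosage.sum()),
                    an=int(called.sum()),
                    n_het=int((dosage == 1).sum()),
                    n_hom_alt=int((dosage == 2).sum()),
                )
            )
    return records


def format_percent(
    af: Fraction | float | int,
    mode: str = "round",
    decimals: int = 2,
) -> str:
    """Format a fraction in [0, 1] as a percentage string.

    ``mode`` is "round" (half-up) or "truncate" (toward zero).  Exact
    arithmetic throughout: 1/2184 gives "0.05" rounded but "0.04"
    truncated.
    """
    frac = af if isinstance(af, Fraction) else Fraction(af)
    if not 0 <= frac <= 1:
        raise FrequencyRangeError(f"allele frequency {af} outside [0, 1]")
    if mode not in ("round", "truncate"):
        raise UsageError(f"mode must be 'round' or 'truncate', got {mode!r}")
    rounding = ROUND_HALF_UP if mode == "round" else ROUND_DOWN
    with localcontext() as ctx:
        ctx.prec = 50
        value = Decimal(frac.numerator) * 100 / Decimal(frac.denominator)
        quantum = Decimal(1).scaleb(-decimals)
        return str(value.quantize(quantum, rounding=rounding))


@dataclass
class ExternalFrequencyTable:
    """Per-ancestry allele frequencies from an external source (gnomAD-style).

    Rows are keyed by (variant label, ancestry group); the variant label
    may be an HGVS c. name or a ``chrom:pos:ref:alt`` string — whatever
    the source table uses.
    """

    rows: dict[tuple[str, str], Fraction]
    source: str = ""

    def freqs_for(self, variant_label: str) -> dict[str, Fraction]:
        """Ancestry → af map for one variant label (empty if unknown)."""
        return {
            ancestry: af
            for (label, ancestry), af in self.rows.items()
            if label == variant_label
        }

    @property
    def variant_labels(self) -> list[str]:
        return sorted({label for label, _ in self.rows})


def _interpret_af(text: str) -> Fraction:
    text = text.strip()
    if text.endswith("%"):
        value = Fraction(text[:-1]) / 100
    else:
        value = Fraction(text)
    if not 0 <= value <= 1:
        raise FrequencyRangeError(
            f"allele frequency {text!r} outside [0, 1] after interpretation "
            "(bare numbers are fractions; append '%' for percentages)"
        )
    return value


def read_external_frequencies(path: str | Path) -> ExternalFrequencyTable:
    """Read an external ancestry-frequency TSV.

    Header ``variant  ancestry  af`` (af as a fraction, or a percentage
    with a trailing "%"), or ``variant  ancestry  ac  an``.  An optional
    ``# source: <label>`` comment line is recorded verbatim.
    """
    path = Path(path)
    source = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            source = first.lstrip("#").strip()
            if source.lower().startswith("source:"):
                source = source[len("source:"):].strip()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = set(df.columns)
    rows: dict[tuple[str, str], Fraction] = {}
    if {"variant", "ancestry", "af"} <= cols:
        for row in df.itertuples(index=False):
            rows[(str(row.variant), str(row.ancestry))] = _interpret_af(str(row.af))
    elif {"variant", "ancestry", "ac", "an"} <= cols:
        for row in df.itertuples(index=False):
            ac, an = int(row.ac), int(row.an)
            if an <= 0 or not 0 <= ac <= an:
                raise FrequencyRangeError(f"bad counts ac={ac} an={an} for {row.variant}")
            rows[(str(row.variant), str(row.ancestry))] = Fraction(ac, an)
    else:
        raise UsageError(
            "external frequency table needs columns (variant, ancestry, af) "
            f"or (variant, ancestry, ac, an); found {sorted(cols)}"
        )
    return ExternalFrequencyTable(rows=rows, source=source)


def frequency_report(
    records: Sequence[AlleleFrequencyRecord],
) -> pd.DataFrame:
    """Tabular frequency report with exact fractions and both percent styles."""
    out = []
    for r in records:
        af = r.af
        out.append(
            {
                "variant": str(r.key),
                "rsid": r.key.rsid or ".",
                "stratum": r.stratum,
                "ac": r.ac,
                "an": r.an,
                "af_exact": f"{r.ac}/{r.an}" if r.an else "undefined",
                "af": float(af) if af is not None else float("nan"),
                "af_pct_rounded": format_percent(af, "round") if af is not None else "",
                "af_pct_truncated": format_percent(af, "truncate") if af is not None else "",
                "n_het": r.n_het,
                "n_hom_alt": r.n_hom_alt,
                "absent": r.absent,
            }
        )
    return pd.DataFrame(out)
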