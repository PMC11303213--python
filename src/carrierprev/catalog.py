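"""Pathogenic-variant catalog loading and cohort intersection.

A catalog (HGMD-export style, as TSV or VCF) lists variants asserted to
cause disease, each with a classification from the five-tier clinical
vocabulary.  :func:`intersect` joins the catalog against a cohort
:class:`~carrierprev.variants.GenotypeMatrix` on the normalized
(chrom, pos, ref, alt) key — never on rsID — and tallies carriers.

A carrier is a sample with at least one non-missing alternate allele at
a matched variant; a homozygote is one carrier, not two.  Carrier status
ignores phase.  A sample carrying two or more distinct matched variants
(or homozygous for one) is flagged "potentially affected" under the
recessive model — a flag, not a diagnosis, since the cohort is healthy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import UsageError, VocabularyError
from .variants import MISSING, GenotypeMatrix, VariantKey, normalize, style_chrom

logger = logging.getLogger(__name__)


class Classification(str, Enum):
    """Five-tier clinical variant classification."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    @classmethod
    def parse(cls, token: str) -> "Classification":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise VocabularyError(
                f"unknown classification token {token!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None

    @property
    def pathogenic_direction(self) -> bool:
        return self in (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC)

    @property
    def benign_direction(self) -> bool:
        return self in (Classification.BENIGN, Classification.LIKELY_BENIGN)


@dataclass(frozen=True)
class CatalogVariant:
    """One catalog entry: a normalized key plus its clinical annotations.

    HGVS c./p. strings are carried as opaque labels; no transcript-level
    validation is attempted.
    """

    key: VariantKey
    cdna_name: str = ""
    protein_name: str = ""
    consequence: str = ""
    asserted_classification: Classification = Classification.PATHOGENIC
    phenotype_note: str = ""


@dataclass(frozen=True)
class ClassificationConflict:
    """Two catalog rows for the same key disagreed on classification."""

    key: VariantKey
    classifications: tuple[Classification, ...]


class Catalog(Sequence):
    """Sequence of :class:`CatalogVariant` plus any collapse conflicts."""

    def __init__(
        self,
        variants: list[CatalogVariant],
        conflicts: list[ClassificationConflict] | None = None,
    ) -> None:
        self._variants = variants
        self.conflicts = conflicts or []

    def __len__(self) -> int:
        return len(self._variants)

    def __getitem__(self, i):
        return self._variants[i]

    def __iter__(self) -> Iterator[CatalogVariant]:
        return iter(self._variants)


_TSV_COLUMNS = {"chrom", "pos", "ref", "alt", "classification"}


def _collapse(raw: list[CatalogVariant]) -> Catalog:
    by_key: dict[VariantKey, list[CatalogVariant]] = {}
    order: list[VariantKey] = []
    for cv in raw:
        if cv.key not in by_key:
            order.append(cv.key)
        by_key.setdefault(cv.key, []).append(cv)
    variants: list[CatalogVariant] = []
    conflicts: list[ClassificationConflict] = []
    for key in order:
        group = by_key[key]
        variants.append(group[0])
        classes = tuple(dict.fromkeys(g.asserted_classification for g in group))
        if len(classes) > 1:
            conflicts.append(ClassificationConflict(key, classes))
            logger.warning(
                "catalog key %s has conflicting classifications %s; keeping first",
                key,
                [c.value for c in classes],
            )
        elif len(group) > 1:
            logger.info("catalog key %s duplicated %d times; collapsed", key, len(group))
    return Catalog(variants, conflicts)


def load_catalog(
    path: str | Path,
    format: str = "tsv",
    chrom_style: str = "chr",
    class_info_key: str = "CLASS",
    phen_info_key: str = "PHEN",
) -> Catalog:
    """Load a pathogenic-variant catalog from TSV or VCF.

    TSV requires a header with at least chrom, pos, ref, alt,
    classification (rsid, cdna, protein, consequence, phenotype are
    optional).  VCF catalogs read classification and phenotype from the
    INFO keys named by ``class_info_key``/``phen_info_key``.  Keys are
    normalized; duplicate keys collapse to one entry, with any
    classification disagreement recorded on ``Catalog.conflicts``.
    """
    path = Path(path)
    raw: list[CatalogVariant] = []
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=sorted(_TSV_COLUMNS))
        missing = _TSV_COLUMNS - set(df.columns)
        if missing and len(df):
            raise UsageError(f"catalog TSV missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            get = lambda name: getattr(row, name, None)
            rsid = get("rsid")
            key = normalize(
                VariantKey(
                    style_chrom(str(row.chrom), chrom_style),
                    int(row.pos),
                    str(row.ref).upper(),
                    str(row.alt).upper(),
                    None if rsid in (None, "", ".") or pd.isna(rsid) else str(rsid),
                )
            )
            raw.append(
                CatalogVariant(
                    key=key,
                    cdna_name=str(get("cdna") or ""),
                    protein_name=str(get("protein") or ""),
                    consequence=str(get("consequence") or ""),
                    asserted_classification=Classification.parse(str(row.classification)),
                    phenotype_note=str(get("phenotype") or ""),
                )
            )
    elif format == "vcf":
        for record in VCF(str(path)):
            rsid = record.ID if record.ID not in (None, ".") else None
            for alt in record.ALT:
                key = normalize(
                    VariantKey(
                        style_chrom(record.CHROM, chrom_style),
                        record.POS,
                        record.REF.upper(),
                        alt.upper(),
                        rsid,
                    )
                )
                cls_token = record.INFO.get(class_info_key) or "pathogenic"
                raw.append(
                    CatalogVariant(
                        key=key,
                        asserted_classification=Classification.parse(str(cls_token)),
                        phenotype_note=str(record.INFO.get(phen_info_key) or ""),
                    )
                )
    else:
        raise UsageError(f"unknown catalog format {format!r}; expected 'tsv' or 'vcf'")
    if not raw:
        logger.warning("catalog %s is empty", path)
    return _collapse(raw)


@dataclass
class IntersectionResult:
    """Catalog variants found in the cohort, and who carries them.

    ``matched`` pairs each found catalog variant with the per-sample
    carrier map (sample ID → alt-allele dosage, carriers only).
    ``carrier_samples`` is the union of carriers over matched variants,
    so a sample carrying both variants counts once.
    """

    matched: list[tuple[CatalogVariant, dict[str, int]]]
    carrier_samples: set[str]
    per_variant_het_count: dict[VariantKey, int]
    per_variant_hom_count: dict[VariantKey, int]
    potentially_affected: set[str] = field(default_factory=set)

    @property
    def matched_keys(self) -> list[VariantKey]:
        return [cv.key for cv, _ in self.matched]

    def carriers_of(self, keys: Sequence[VariantKey]) -> set[str]:
        """Distinct carriers restricted to a subset of matched keys."""
        wanted = set(keys)
        out: set[str] = set()
        for cv, carrier_map in self.matched:
            if cv.key in wanted:
                out.update(carrier_map)
        return out


def intersect(cohort: GenotypeMatrix, catalog: Sequence[CatalogVariant]) -> IntersectionResult:
    """Identify catalog variants present in the cohort and their carriers.

    Matching is exact on the normalized (chrom, pos, ref, alt) key.  An
    empty intersection is a valid result.
    """
    index = {key: i for i, key in enumerate(cohort.variants)}
    matched: list[tuple[CatalogVariant, dict[str, int]]] = []
    het: dict[VariantKey, int] = {}
    hom: dict[VariantKey, int] = {}
    carriers: set[str] = set()
    carried_distinct: dict[str, int] = {}
    affected: set[str] = set()
    for cv in catalog:
        i = index.get(cv.key)
        if i is None:
            continue
        dosage = cohort.alt_dosage(i)
        carrier_map = {
            cohort.samples[j]: int(dosage[j]) for j in np.flatnonzero(dosage > 0)
        }
        matched.append((cv, carrier_map))
        het[cv.key] = int((dosage == 1).sum())
        hom[cv.key] = int((dosage == 2).sum())
        for sample, d in carrier_map.items():
            carriers.add(sample)
            carried_distinct[sample] = carried_distinct.get(sample, 0) + 1
            if d >= 2:
                affected.add(sample)
    affected |= {s for s, k in carried_distinct.items() if k >= 2}
    return IntersectionResult(
        matched=matched,
        carrier_samples=carriers,
        per_variant_het_count=het,
        per_variant_hom_count=hom,
        potentially_affected=affected,
    )
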