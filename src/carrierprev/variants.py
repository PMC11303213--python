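"""Cohort VCF and sample-panel I/O, variant-key normalization.

The central identity in the pipeline is :class:`VariantKey` — chromosome,
1-based position, reference and alternate allele, all on GRCh37.  Cohort
genotypes live in a :class:`GenotypeMatrix` (diploid calls, missing allowed
per allele slot), and ancestry labels come from a :class:`SamplePanel` in
the 1000 Genomes two-level (subpopulation → superpopulation) dialect.

Coordinates are 1-based inclusive everywhere (VCF convention); region
arguments are half-open ``[start, end)`` so adjacent subsets tile without
overlap.  Genotype phase is parsed and discarded: no downstream count uses
phase.  Chromosome-name dialects ("17" vs "chr17") are unified at parse
time via ``chrom_style``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import (
    EmptyPanelError,
    InvalidVariantError,
    PanelConflictError,
    PanelParseError,
    VcfParseError,
    VcfStructureError,
)

logger = logging.getLogger(__name__)

MISSING = -1  # missing allele slot in GenotypeMatrix.calls

_ACGT = frozenset("ACGT")

GENOME_BUILD = "GRCh37"


def style_chrom(chrom: str, chrom_style: str = "chr") -> str:
    """Unify chromosome-name dialects.

    ``chrom_style``: "chr" adds the chr prefix, "plain" strips it,
    "as-is" leaves the input untouched.
    """
    if chrom_style == "as-is":
        return chrom
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if chrom_style == "chr" else bare


@dataclass(frozen=True)
class VariantKey:
    """Normalized genomic identity of a biallelic variant.

    Equality and hashing use (chrom, pos, ref, alt) only; ``rsid`` is
    carried for reporting but is never a join key (dbSNP identifiers
    drift across builds).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidVariantError(f"position must be >= 1, got {self.pos}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _ACGT:
                raise InvalidVariantError(
                    f"{label} allele must be a non-empty uppercase ACGT string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise InvalidVariantError(
                f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, text: str) -> "VariantKey":
        """Parse a ``chrom:pos:ref:alt`` string."""
        parts = text.split(":")
        if len(parts) != 4:
            raise InvalidVariantError(f"expected chrom:pos:ref:alt, got {text!r}")
        return cls(parts[0], int(parts[1]), parts[2].upper(), parts[3].upper())


def normalize(
    key: VariantKey,
    reference_context: Callable[[int], str] | None = None,
) -> VariantKey:
    """Canonicalize a variant key.

    Trims the shared allele suffix, then the shared prefix, keeping at
    least one base of each allele and adjusting ``pos``.  When a
    ``reference_context`` (1-based position → base) is supplied, indels
    are additionally left-aligned by the usual shift-left procedure:
    while both alleles end in the same base, prepend the reference base
    to the left and drop the shared last base.  SNVs come back unchanged.
    Idempotent.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    if ref == alt:
        raise InvalidVariantError(f"ref == alt for {key}")
    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
                changed = True
            elif reference_context is not None and pos > 1:
                base = reference_context(pos - 1).upper()
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
                changed = True
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
    if ref == alt:
        raise InvalidVariantError(f"ref == alt after trimming for {key}")
    return VariantKey(key.chrom, pos, ref, alt, key.rsid)


@dataclass
class GenotypeMatrix:
    """Per-sample diploid allele calls for a set of biallelic variants.

    ``calls`` has shape (n_variants, n_samples, 2) with entries in
    {0, 1, MISSING}.  Multiallelic records have already been decomposed
    at read time, so allele index 1 always means "the alt of this key".
    """

    samples: list[str]
    variants: list[VariantKey]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples), 2):
            raise VcfStructureError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples x 2"
            )
        if len(set(self.samples)) != len(self.samples):
            raise VcfStructureError("duplicate sample IDs")
        if len(set(self.variants)) != len(self.variants):
            raise VcfStructureError("duplicate variant keys")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise VcfStructureError("allele indices must be 0, 1 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, key: VariantKey) -> int:
        return self.variants.index(key)

    def alt_dosage(self, variant_index: int) -> np.ndarray:
        """Per-sample count of alt alleles (missing slots contribute 0)."""
        v = self.calls[variant_index]
        return (v == 1).sum(axis=1)

    def called_alleles(self, variant_index: int) -> np.ndarray:
        """Per-sample count of non-missing allele slots."""
        v = self.calls[variant_index]
        return (v != MISSING).sum(axis=1)


@dataclass
class SamplePanel:
    """Sample → (subpopulation, superpopulation) assignments.

    Enforces the two-level 1000 Genomes structure: every subpopulation
    maps to exactly one superpopulation.
    """

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        sub_to_super: dict[str, str] = {}
        for sample, (sub, sup) in self.entries.items():
            prev = sub_to_super.setdefault(sub, sup)
            if prev != sup:
                raise PanelConflictError(
                    f"subpopulation {sub} maps to both {prev} and {sup} (sample {sample})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sample: str) -> bool:
        return sample in self.entries

    @property
    def subpopulations(self) -> dict[str, str]:
        """subpopulation code → superpopulation code."""
        return {sub: sup for sub, sup in self.entries.values()}

    @property
    def superpopulations(self) -> list[str]:
        return sorted({sup for _, sup in self.entries.values()})

    def samples_in(self, stratum: str) -> list[str]:
        """Sample IDs in a stratum ("ALL", a superpopulation, or a subpopulation)."""
        if stratum == "ALL":
            return list(self.entries)
        return [
            s for s, (sub, sup) in self.entries.items() if stratum in (sub, sup)
        ]


def read_panel(path: str | Path) -> SamplePanel:
    """Read a 1000 Genomes-style panel file.

    Whitespace-separated lines ``sample subpop superpop [extras...]``;
    extra trailing columns (e.g. sequencing platform) are ignored.
    Duplicate lines with identical assignment collapse silently;
    conflicting duplicates raise :class:`PanelConflictError`.
    """
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PanelParseError(
                    f"line {lineno}: expected at least 3 fields "
                    f"(sample, subpop, superpop), got {len(fields)}"
                )
            sample, sub, sup = fields[0], fields[1], fields[2]
            if sample in entries and entries[sample] != (sub, sup):
                raise PanelConflictError(
                    f"line {lineno}: sample {sample} assigned to both "
                    f"{entries[sample]} and {(sub, sup)}"
                )
            entries[sample] = (sub, sup)
    if not entries:
        raise EmptyPanelError(f"panel file {path} contains no sample entries")
    return SamplePanel(entries)


def write_panel(panel: SamplePanel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sample, (sub, sup) in panel.entries.items():
            fh.write(f"{sample}\t{sub}\t{sup}\n")
    return path


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _structural_scan(path: Path) -> int:
    """Validate VCF line structure, returning the header sample count.

    htslib does not report line numbers on parse failure, so this cheap
    pre-pass provides the diagnostics: every data line must have
    9 + n_samples tab-separated fields and an integer POS.
    """
    n_samples: int | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 9:
                    raise VcfParseError(
                        f"line {lineno}: #CHROM header has {len(cols)} columns, expected >= 9"
                    )
                n_samples = len(cols) - 9
                continue
            if n_samples is None:
                raise VcfParseError(f"line {lineno}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + n_samples:
                if len(fields) >= 8:
                    raise VcfStructureError(
                        f"line {lineno}: {len(fields) - 9} genotype columns, "
                        f"header declares {n_samples} samples"
                    )
                raise VcfParseError(
                    f"line {lineno}: malformed VCF record with {len(fields)} fields"
                )
            try:
                int(fields[1])
            except ValueError:
                raise VcfParseError(
                    f"line {lineno}: POS field {fields[1]!r} is not an integer"
                ) from None
    if n_samples is None:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    return n_samples


def _overlaps(pos: int, ref: str, region: tuple[str, int, int], chrom: str) -> bool:
    rchrom, start, end = region
    if style_chrom(chrom, "plain") != style_chrom(rchrom, "plain"):
        return False
    return pos < end and pos + len(ref) - 1 >= start


def read_cohort_vcf(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    chrom_style: str = "chr",
) -> GenotypeMatrix:
    """Read a diploid cohort VCF into a :class:`GenotypeMatrix`.

    ``region`` is a half-open 1-based interval ``(chrom, start, end)``;
    only records overlapping it are returned.  Multiallelic records are
    decomposed into one biallelic record per alt allele: for the record
    carrying alt *k*, a sample allele equal to *k* recodes to 1, the
    reference to 0, and any *other* alt to missing (an other-alt slot
    carries no information about this alt and must not inflate the
    reference count).  Phase separators "|" and "/" are both accepted
    and phase is discarded.
    """
    path = Path(path)
    if region is not None and not region[1] < region[2]:
        raise ValueError(f"region start must be < end, got {region}")
    n_header_samples = _structural_scan(path)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if len(samples) != n_header_samples:  # pragma: no cover - htslib agrees with scan
        raise VcfStructureError(
            f"header declares {n_header_samples} samples, parser sees {len(samples)}"
        )

    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    seen: set[VariantKey] = set()
    for record in vcf:
        if region is not None and not _overlaps(record.POS, record.REF, region, record.CHROM):
            continue
        gts = record.genotype.array()  # (n_samples, ploidy+1); last col = phase
        if gts.shape[1] - 1 != 2:
            raise VcfStructureError(
                f"{record.CHROM}:{record.POS}: ploidy {gts.shape[1] - 1}, only diploid supported"
            )
        alleles = gts[:, :2].astype(np.int16)  # -1 encodes missing
        chrom = style_chrom(record.CHROM, chrom_style)
        rsid = record.ID if record.ID not in (None, ".") else None
        for alt_index, alt in enumerate(record.ALT, start=1):
            if set(alt.upper()) - _ACGT:
                logger.warning(
                    "skipping non-ACGT alt %s at %s:%s", alt, record.CHROM, record.POS
                )
                continue
            key = normalize(VariantKey(chrom, record.POS, record.REF.upper(), alt.upper(), rsid))
            recoded = np.full(alleles.shape, MISSING, dtype=np.int8)
            recoded[alleles == 0] = 0
            recoded[alleles == alt_index] = 1
            # other alt indices and missing stay MISSING
            if key in seen:
                logger.warning("duplicate record for %s; keeping first", key)
                continue
            seen.add(key)
            keys.append(key)
            rows.append(recoded)
    calls = (
        np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=keys, calls=calls)


def write_cohort_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    phased: bool = False,
) -> Path:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT only).

    Records are written in matrix order; missing allele slots become ".".
    The genome build is recorded in the header.
    """
    path = Path(path)
    sep = "|" if phased else "/"
    contigs = dict(contig_lengths or {})
    for key in matrix.variants:
        contigs.setdefault(key.chrom, 0)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={GENOME_BUILD}\n")
        for chrom, length in contigs.items():
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, key in enumerate(matrix.variants):
            gts = []
            for a, b in matrix.calls[i]:
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                gts.append(f"{sa}{sep}{sb}")
            rsid = key.rsid or "."
            fh.write(
                f"{key.chrom}\t{key.pos}\t{rsid}\t{key.ref}\t{key.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path
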