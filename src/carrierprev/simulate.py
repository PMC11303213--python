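"""Seeded synthetic fixtures emulating the study conditions.

The default fixture mirrors a healthy reference cohort of 1092 diploid
individuals in 14 subpopulations under 4 superpopulations (the 1000
Genomes Phase 1 panel composition), carrying 444 unique variants in the
CTNS region of chromosome 17 (GRCh37), together with a 75-entry
pathogenic-variant catalog.  Exactly two catalog variants are present in
the cohort: the atypical-disease missense allele chr17:3550800 G>A
(c.124G>A, p.Val42Ile) in 35 heterozygotes drawn preferentially from
African-ancestry samples, and the severe infantile allele chr17:3559792
T>C (c.473T>C, p.Leu158Pro) in a single heterozygote.  The remaining 442
cohort variants are background SNVs absent from the catalog, and the 73
catalog decoys are absent from the cohort.  An external gnomAD-style
table supplies per-ancestry frequencies for the common allele (AFR
6.26%, NFE 0.006%, FIN 0%, Asian 0.002%).

Everything is deterministic given the seed: two runs with the same spec
produce byte-identical files.  No linkage disequilibrium, relatedness or
sequencing error is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import FeasibilityError
from .variants import (
    GENOME_BUILD,
    MISSING,
    GenotypeMatrix,
    SamplePanel,
    VariantKey,
    write_cohort_vcf,
)

_ACGT = "ACGT"

#: 1000 Genomes Phase 1 panel composition: subpopulation -> (superpopulation, n)
PHASE1_COMPOSITION: dict[str, tuple[str, int]] = {
    "ASW": ("AFR", 61), "LWK": ("AFR", 97), "YRI": ("AFR", 88),
    "CLM": ("AMR", 60), "MXL": ("AMR", 66), "PUR": ("AMR", 55),
    "CHB": ("EAS", 97), "CHS": ("EAS", 100), "JPT": ("EAS", 89),
    "CEU": ("EUR", 85), "FIN": ("EUR", 93), "GBR": ("EUR", 89),
    "IBS": ("EUR", 14), "TSI": ("EUR", 98),
}

#: CTNS locus on GRCh37, half-open
DEFAULT_REGION: tuple[str, int, int] = ("chr17", 3539771, 3564700)


class OverlapSpec(BaseModel):
    """One variant present in both cohort and catalog, with its carriers."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    cdna_name: str = ""
    protein_name: str = ""
    consequence: str = "missense"
    classification: str = "pathogenic"
    phenotype_note: str = ""
    het_carriers: int = 0
    hom_carriers: int = 0
    #: sampling weight per superpopulation for carrier placement
    superpop_weights: dict[str, float] = Field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt, self.rsid)


def _default_overlaps() -> list[OverlapSpec]:
    return [
        OverlapSpec(
            chrom="chr17", pos=3550800, ref="G", alt="A", rsid="rs35086888",
            cdna_name="c.124G>A", protein_name="p.Val42Ile",
            consequence="missense", classification="pathogenic",
            phenotype_note="atypical cystinosis",
            het_carriers=35,
            superpop_weights={"AFR": 0.9, "AMR": 0.1 / 3, "EAS": 0.1 / 3, "EUR": 0.1 / 3},
        ),
        OverlapSpec(
            chrom="chr17", pos=3559792, ref="T", alt="C", rsid="rs113994206",
            cdna_name="c.473T>C", protein_name="p.Leu158Pro",
            consequence="missense", classification="pathogenic",
            phenotype_note="infantile nephropathic cystinosis",
            het_carriers=1,
        ),
    ]


#: the per-ancestry frequencies published for the common allele
DEFAULT_EXTERNAL_ROWS: list[tuple[str, str, str]] = [
    ("c.124G>A", "AFR", "6.26%"),
    ("c.124G>A", "NFE", "0.006%"),
    ("c.124G>A", "FIN", "0%"),
    ("c.124G>A", "Asian", "0.002%"),
]


class FixtureSpec(BaseModel):
    """Parameters of the synthetic study fixture."""

    n_samples: int = 1092
    composition: dict[str, tuple[str, int]] = Field(
        default_factory=lambda: dict(PHASE1_COMPOSITION)
    )
    n_cohort_variants: int = 444
    n_catalog_variants: int = 75
    overlaps: list[OverlapSpec] = Field(default_factory=_default_overlaps)
    region: tuple[str, int, int] = DEFAULT_REGION
    external_rows: list[tuple[str, str, str]] = Field(
        default_factory=lambda: list(DEFAULT_EXTERNAL_ROWS)
    )
    external_source: str = "synthetic gnomAD-style ancestry table"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        total = sum(n for _, n in self.composition.values())
        if total != self.n_samples:
            raise FeasibilityError(
                f"subpopulation counts sum to {total}, expected n_samples={self.n_samples}"
            )
        keys = [ov.key for ov in self.overlaps]
        if len(set(keys)) != len(keys):
            raise FeasibilityError("overlap keys must be unique")
        chrom, start, end = self.region
        for ov in self.overlaps:
            if ov.chrom != chrom or not start <= ov.pos < end:
                raise FeasibilityError(f"overlap {ov.key} outside region {self.region}")
            if ov.het_carriers + ov.hom_carriers > self.n_samples:
                raise FeasibilityError(f"more carriers than samples for {ov.key}")
        if len(self.overlaps) > self.n_cohort_variants:
            raise FeasibilityError("more overlaps than cohort variants")
        if len(self.overlaps) > self.n_catalog_variants:
            raise FeasibilityError("more overlaps than catalog variants")
        n_positions = end - start
        if self.n_cohort_variants + self.n_catalog_variants > n_positions:
            raise FeasibilityError("region too small for requested variant counts")
        return self


@dataclass
class FixturePaths:
    cohort_vcf: Path
    panel: Path
    catalog: Path
    external_freq: Path
    metadata: Path


def _build_samples(spec: FixtureSpec) -> tuple[list[str], dict[str, tuple[str, str]]]:
    samples: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    counter = 1
    for sub, (sup, n) in spec.composition.items():
        for _ in range(n):
            sid = f"HG{counter:05d}"
            samples.append(sid)
            entries[sid] = (sub, sup)
            counter += 1
    return samples, entries


def _place_carriers(
    ov: OverlapSpec,
    samples: list[str],
    entries: dict[str, tuple[str, str]],
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Pick hom and het carrier sample indices by superpopulation weight."""
    n = len(samples)
    need = ov.het_carriers + ov.hom_carriers
    if ov.superpop_weights:
        sup_counts: dict[str, int] = {}
        for sid in samples:
            sup_counts[entries[sid][1]] = sup_counts.get(entries[sid][1], 0) + 1
        w = np.array(
            [
                ov.superpop_weights.get(entries[sid][1], 0.0)
                / sup_counts[entries[sid][1]]
                for sid in samples
            ]
        )
        if (w > 0).sum() < need:
            raise FeasibilityError(
                f"{need} carriers requested for {ov.key} but only "
                f"{int((w > 0).sum())} samples have positive weight"
            )
        w = w / w.sum()
        chosen = rng.choice(n, size=need, replace=False, p=w)
    else:
        chosen = rng.choice(n, size=need, replace=False)
    chosen = list(int(c) for c in chosen)
    return chosen[: ov.hom_carriers], chosen[ov.hom_carriers:]


def _background_genotypes(
    n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Rare-variant genotypes: per-site af log-uniform in [1/(2N), 2%]."""
    lo, hi = np.log10(1.0 / (2 * n_samples)), np.log10(0.02)
    af = 10 ** rng.uniform(lo, hi)
    calls = (rng.random((n_samples, 2)) < af).astype(np.int8)
    if calls.sum() == 0:
        calls[rng.integers(n_samples), rng.integers(2)] = 1  # every site is observed
    return calls


def build_fixture_matrix(spec: FixtureSpec) -> tuple[GenotypeMatrix, SamplePanel, dict]:
    """Construct the in-memory cohort, panel and placement metadata."""
    rng = np.random.default_rng(spec.seed)
    samples, entries = _build_samples(spec)
    panel = SamplePanel(entries)
    chrom, start, end = spec.region

    overlap_pos = {ov.pos for ov in spec.overlaps}
    n_background = spec.n_cohort_variants - len(spec.overlaps)
    candidates = np.setdiff1d(
        np.arange(start, end), np.fromiter(overlap_pos, dtype=np.int64)
    )
    bg_pos = np.sort(rng.choice(candidates, size=n_background, replace=False))

    variants: list[tuple[VariantKey, np.ndarray]] = []
    placement: dict[str, dict] = {}
    for ov in spec.overlaps:
        calls = np.zeros((len(samples), 2), dtype=np.int8)
        hom_idx, het_idx = _place_carriers(ov, samples, entries, rng)
        for j in hom_idx:
            calls[j] = (1, 1)
        for j in het_idx:
            calls[j, rng.integers(2)] = 1  # random haplotype; phase is cosmetic
        variants.append((ov.key, calls))
        by_sup: dict[str, int] = {}
        for j in het_idx + hom_idx:
            sup = entries[samples[j]][1]
            by_sup[sup] = by_sup.get(sup, 0) + 1
        placement[str(ov.key)] = {
            "het_carriers": ov.het_carriers,
            "hom_carriers": ov.hom_carriers,
            "carriers_by_superpopulation": dict(sorted(by_sup.items())),
        }
    for pos in bg_pos:
        ref = _ACGT[rng.integers(4)]
        alt = rng.choice([b for b in _ACGT if b != ref])
        variants.append(
            (VariantKey(chrom, int(pos), ref, str(alt)), _background_genotypes(len(samples), rng))
        )
    variants.sort(key=lambda kv: kv[0].pos)
    matrix = GenotypeMatrix(
        samples=samples,
        variants=[k for k, _ in variants],
        calls=np.stack([c for _, c in variants]),
    )
    meta = {
        "genome_build": GENOME_BUILD,
        "region": list(spec.region),
        "n_samples": spec.n_samples,
        "n_cohort_variants": spec.n_cohort_variants,
        "n_catalog_variants": spec.n_catalog_variants,
        "seed": spec.seed,
        "overlap_placement": placement,
        "note": (
            "carrier placement across subpopulations is one draw consistent "
            "with the pooled counts; only pooled counts are constrained"
        ),
    }
    return matrix, panel, meta


def _decoy_catalog_rows(
    spec: FixtureSpec, cohort_positions: set[int], rng: np.random.Generator
) -> list[dict]:
    chrom, start, end = spec.region
    n_decoys = spec.n_catalog_variants - len(spec.overlaps)
    candidates = np.setdiff1d(
        np.arange(start, end), np.fromiter(cohort_positions, dtype=np.int64)
    )
    decoy_pos = np.sort(rng.choice(candidates, size=n_decoys, replace=False))
    consequences = ["missense", "nonsense", "frameshift", "splice"]
    rows = []
    for i, pos in enumerate(decoy_pos):
        ref = _ACGT[rng.integers(4)]
        alt = str(rng.choice([b for b in _ACGT if b != ref]))
        cls = "pathogenic" if rng.random() < 0.8 else "likely_pathogenic"
        rows.append(
            {
                "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt, "rsid": ".",
                "cdna": f"c.{int(pos) - start + 1}{ref}>{alt}",
                "protein": ".",
                "consequence": consequences[int(rng.integers(len(consequences)))],
                "classification": cls,
                "phenotype": "cystinosis",
            }
        )
    return rows


def generate_fixture(spec: FixtureSpec | None = None, out_dir: str | Path = ".") -> FixturePaths:
    """Write the four fixture files (plus metadata JSON) to ``out_dir``.

    Returns the paths to the cohort VCF, the sample panel, the catalog
    TSV and the external-frequency TSV.  Byte-identical for identical
    spec + seed.
    """
    spec = spec or FixtureSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, panel, meta = build_fixture_matrix(spec)

    cohort_path = out_dir / "cohort.vcf"
    write_cohort_vcf(
        matrix, cohort_path,
        contig_lengths={spec.region[0]: 81195210},  # chr17, GRCh37
        phased=True,
    )
    panel_path = out_dir / "samples.panel"
    with open(panel_path, "w") as fh:
        for sample, (sub, sup) in panel.entries.items():
            fh.write(f"{sample}\t{sub}\t{sup}\tILLUMINA\n")  # trailing platform column, as in the wild

    # catalog: the overlap variants plus decoys absent from the cohort
    rng = np.random.default_rng(spec.seed + 1)  # separate stream; cohort already fixed
    cohort_positions = {k.pos for k in matrix.variants}
    rows = [
        {
            "chrom": ov.chrom, "pos": ov.pos, "ref": ov.ref, "alt": ov.alt,
            "rsid": ov.rsid or ".", "cdna": ov.cdna_name, "protein": ov.protein_name,
            "consequence": ov.consequence, "classification": ov.classification,
            "phenotype": ov.phenotype_note,
        }
        for ov in spec.overlaps
    ] + _decoy_catalog_rows(spec, cohort_positions, rng)
    rows.sort(key=lambda r: r["pos"])
    catalog_path = out_dir / "catalog.tsv"
    header = ["chrom", "pos", "ref", "alt", "rsid", "cdna", "protein",
              "consequence", "classification", "phenotype"]
    with open(catalog_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in header) + "\n")

    freq_path = out_dir / "external_frequencies.tsv"
    with open(freq_path, "w") as fh:
        fh.write(f"# source: {spec.external_source}\n")
        fh.write("variant\tancestry\taf\n")
        for variant, ancestry, af in spec.external_rows:
            fh.write(f"{variant}\t{ancestry}\t{af}\n")

    meta_path = out_dir / "fixture_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return FixturePaths(cohort_path, panel_path, catalog_path, freq_path, meta_path)


def generate_random_cohort(
    n_samples: int,
    n_variants: int,
    seed: int,
    af: float | None = None,
    missing_rate: float = 0.0,
    chrom: str = "chr17",
    start: int = 1000,
    n_subpops: int = 4,
    n_superpops: int = 2,
) -> tuple[GenotypeMatrix, SamplePanel]:
    """Small random cohort for property tests.

    Genotype allele slots are drawn Bernoulli(af) per variant; when
    ``af`` is None each variant samples its own frequency from
    Beta(0.5, 5).  Samples are dealt round-robin into ``n_subpops``
    subpopulations nested in ``n_superpops`` superpopulations.
    """
    if n_samples < 1 or n_variants < 1:
        raise FeasibilityError("need at least one sample and one variant")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    entries = {
        s: (f"P{i % n_subpops}", f"SUP{(i % n_subpops) % n_superpops}")
        for i, s in enumerate(samples)
    }
    panel = SamplePanel(entries)
    keys = []
    calls = np.zeros((n_variants, n_samples, 2), dtype=np.int8)
    for v in range(n_variants):
        site_af = float(rng.beta(0.5, 5)) if af is None else af
        calls[v] = (rng.random((n_samples, 2)) < site_af).astype(np.int8)
        if missing_rate > 0:
            calls[v][rng.random((n_samples, 2)) < missing_rate] = MISSING
        ref = _ACGT[rng.integers(4)]
        alt = str(rng.choice([b for b in _ACGT if b != ref]))
        keys.append(VariantKey(chrom, start + v, ref, alt))
    return GenotypeMatrix(samples=samples, variants=keys, calls=calls), panel
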