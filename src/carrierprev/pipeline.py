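"""End-to-end pipeline: read → intersect → frequencies → evidence → scenarios.

:func:`run_pipeline` executes every stage from a single declarative
:class:`RunConfig` and writes four TSV reports plus a JSON run summary
(tool version, input hashes, full config) to the output directory.
Reports contain no timestamps, so re-running an identical config on
identical inputs reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from fractions import Fraction
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .acmg import EvidenceThresholds, assign_evidence, reconcile
from .catalog import intersect, load_catalog
from .errors import CarrierPrevError
from .popfreq import (
    DEFAULT_ANCESTRY_MAP,
    format_percent,
    frequency_report,
    read_external_frequencies,
    stratified_frequencies,
)
from .prevalence import NEVER, sensitivity_scenarios
from .variants import GENOME_BUILD, VariantKey, read_cohort_vcf, read_panel

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Declarative configuration of one pipeline run."""

    vcf: Path
    panel: Path
    catalog: Path
    catalog_format: Literal["tsv", "vcf"] = "tsv"
    freq_table: Optional[Path] = None
    region: Optional[tuple[str, int, int]] = None
    chrom_style: Literal["chr", "plain", "as-is"] = "chr"
    ba1: str = "0.05"
    bs1: Optional[str] = None
    pm2_max: Optional[str] = None
    policy: Literal["all", "acmg_filtered", "leave_one_out", "explicit"] = "all"
    explicit_keys: list[str] = Field(default_factory=list)
    ancestry_map: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_ANCESTRY_MAP))
    out_dir: Path = Path("carrierprev_out")
    decimals: int = 2
    log_level: str = "INFO"

    @field_validator("ba1", "bs1", "pm2_max", mode="before")
    @classmethod
    def _threshold_as_str(cls, v):
        # thresholds are kept as decimal strings so 0.05 stays exactly 1/20
        return None if v is None else str(v)

    def thresholds(self) -> EvidenceThresholds:
        return EvidenceThresholds(
            ba1=Fraction(self.ba1),
            bs1=None if self.bs1 is None else Fraction(self.bs1),
            pm2_max=None if self.pm2_max is None else Fraction(self.pm2_max),
        )

    def validate_inputs(self) -> None:
        for label, path in (("vcf", self.vcf), ("panel", self.panel), ("catalog", self.catalog)):
            if not Path(path).exists():
                raise CarrierPrevError(f"config: {label} path does not exist: {path}")
        if self.freq_table is not None and not Path(self.freq_table).exists():
            raise CarrierPrevError(f"config: freq_table path does not exist: {self.freq_table}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _stage(name: str):
    """Decorator-ish context: re-raise stage failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, CarrierPrevError):
                raise CarrierPrevError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, CarrierPrevError):
                raise CarrierPrevError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write reports; returns the run summary dict."""
    logging.basicConfig(level=config.log_level.upper())
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        cohort = read_cohort_vcf(config.vcf, region=config.region, chrom_style=config.chrom_style)
        panel = read_panel(config.panel)
        catalog = load_catalog(config.catalog, format=config.catalog_format,
                               chrom_style=config.chrom_style)
        external = (
            read_external_frequencies(config.freq_table)
            if config.freq_table is not None
            else None
        )

    with _stage("intersect"):
        result = intersect(cohort, catalog)

    with _stage("frequencies"):
        records = stratified_frequencies(cohort, panel, result.matched_keys)

    with _stage("evidence"):
        thresholds = config.thresholds()
        assignments = {}
        for cv, _ in result.matched:
            freqs = {}
            if external is not None:
                freqs = external.freqs_for(cv.cdna_name) or external.freqs_for(str(cv.key))
            if not freqs:
                # fall back to cohort superpopulation frequencies
                freqs = {
                    r.stratum: r.af
                    for r in records
                    if r.key == cv.key and r.stratum in panel.superpopulations
                    and r.af is not None
                }
            assignments[cv.key] = assign_evidence(freqs, thresholds, key=cv.key)

    with _stage("reconcile"):
        reconciliations = [
            reconcile(assignments[cv.key], cv) for cv, _ in result.matched
        ]

    with _stage("scenarios"):
        explicit = [VariantKey.from_string(s) for s in config.explicit_keys]
        scenarios = sensitivity_scenarios(
            records,
            result,
            reconciliations,
            policy=config.policy,
            explicit_keys=explicit,
            cohort_size=cohort.n_samples,
        )

    with _stage("report"):
        inter_rows = []
        all_records = {(r.key, r.stratum): r for r in records}
        for cv, carrier_map in result.matched:
            rec = all_records[(cv.key, "ALL")]
            af = rec.af
            inter_rows.append({
                "chrom": cv.key.chrom, "pos": cv.key.pos,
                "rsid": cv.key.rsid or ".", "ref": cv.key.ref, "alt": cv.key.alt,
                "cdna": cv.cdna_name, "protein": cv.protein_name,
                "consequence": cv.consequence,
                "classification": cv.asserted_classification.value,
                "phenotype": cv.phenotype_note,
                "n_carriers": len(carrier_map),
                "n_het": result.per_variant_het_count[cv.key],
                "n_hom": result.per_variant_hom_count[cv.key],
                "ac": rec.ac, "an": rec.an,
                "af_pct_rounded": format_percent(af, "round", config.decimals) if af is not None else "",
            })
        _write_tsv(pd.DataFrame(inter_rows), out / "intersection_report.tsv")
        _write_tsv(frequency_report(records), out / "frequency_report.tsv")

        rec_rows = []
        for r in reconciliations:
            strata = "; ".join(
                f"{code}:{group}={float(af):.6g}"
                for code, hits in sorted(r.triggering_strata.items())
                for group, af in hits
            )
            rec_rows.append({
                "variant": str(r.key),
                "asserted": r.asserted.value,
                "frequency_classification": r.frequency_classification,
                "triggered": ",".join(r.triggered) or ".",
                "triggering_strata": strata or ".",
                "verdict": r.verdict,
            })
        _write_tsv(pd.DataFrame(rec_rows), out / "reconciliation_report.tsv")

        prev_rows = []
        for est in scenarios:
            d = est.as_dict()
            prev_rows.append({
                "scenario": est.scenario_label,
                "included_variants": ";".join(str(k) for k in est.included_keys) or ".",
                "q_exact": d["q"]["exact"],
                "q_pct_truncated": format_percent(est.q, "truncate", config.decimals),
                "q_pct_rounded": format_percent(est.q, "round", config.decimals),
                "carrier_rate_hwe": float(est.carrier_rate_hwe),
                "one_in_carrier_hwe": str(est.one_in_carrier_hwe),
                "carrier_rate_observed": (
                    float(est.carrier_rate_observed)
                    if est.carrier_rate_observed is not None else ""
                ),
                "one_in_carrier_observed": str(est.one_in_carrier_observed),
                "affected_rate": float(est.affected_rate),
                "one_in_affected": str(est.one_in_affected),
                "genome_build": GENOME_BUILD,
            })
        _write_tsv(pd.DataFrame(prev_rows), out / "prevalence_report.tsv")
        with open(out / "prevalence_report.json", "w") as fh:
            json.dump([e.as_dict() for e in scenarios], fh, indent=2, sort_keys=True)
            fh.write("\n")

        summary = {
            "tool": "carrierprev",
            "version": __version__,
            "genome_build": GENOME_BUILD,
            "config": json.loads(config.model_dump_json()),
            "input_sha256": {
                "vcf": _sha256(config.vcf),
                "panel": _sha256(config.panel),
                "catalog": _sha256(config.catalog),
                **(
                    {"freq_table": _sha256(config.freq_table)}
                    if config.freq_table is not None else {}
                ),
            },
            "n_cohort_samples": cohort.n_samples,
            "n_cohort_variants": cohort.n_variants,
            "n_catalog_variants": len(catalog),
            "n_matched_variants": len(result.matched),
            "n_carrier_samples": len(result.carrier_samples),
            "n_potentially_affected": len(result.potentially_affected),
            "external_source": external.source if external is not None else None,
            "scenarios": [e.as_dict() for e in scenarios],
        }
        with open(out / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
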