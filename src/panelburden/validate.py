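"""Schema and cross-reference validation for the four input tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CLINICAL_CLASSES, CONSEQUENCES

__all__ = ["ValidationReport", "validate_inputs", "validate_frames"]

MAX_ROWS_REPORTED = 10


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, table: str, message: str, rows: pd.DataFrame | None = None) -> None:
        detail = ""
        if rows is not None and len(rows):
            detail = " first offending rows: " + rows.head(MAX_ROWS_REPORTED).to_dict("records").__repr__()
        self.errors.append(f"[{table}] {message}.{detail}")

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ValueError("input validation failed:\n" + "\n".join(self.errors))

    def __str__(self) -> str:
        if self.ok:
            return "validation passed"
        return "\n".join(self.errors)


def _check_phenotypes(phen: pd.DataFrame, report: ValidationReport) -> None:
    required = {"subject_id", "status", "age_years", "family_history", "er", "pr", "her2"}
    if missing := required - set(phen.columns):
        report.add("phenotypes", f"missing columns {sorted(missing)}")
        return
    dup = phen[phen["subject_id"].duplicated(keep=False)]
    if len(dup):
        report.add("phenotypes", "duplicate subject_id", dup)
    bad_status = phen[~phen["status"].isin(["case", "control"])]
    if len(bad_status):
        report.add("phenotypes", "status must be 'case' or 'control'", bad_status)
    age = pd.to_numeric(phen["age_years"], errors="coerce")
    bad_age = phen[age.isna() | (age < 18) | (age > 120)]
    if len(bad_age):
        report.add("phenotypes", "age_years must be a number in [18, 120]", bad_age)
    fh = pd.to_numeric(phen["family_history"], errors="coerce")
    bad_fh = phen[~(fh.isin([0.0, 1.0]) | phen["family_history"].isna())]
    if len(bad_fh):
        report.add("phenotypes", "family_history must be 0, 1 or missing", bad_fh)
    for marker in ("er", "pr", "her2"):
        bad = phen[~phen[marker].astype(str).isin(["pos", "neg", "NA", "nan", "<NA>"])]
        if len(bad):
            report.add("phenotypes", f"{marker} must be pos/neg/NA", bad)


def _check_variants(var: pd.DataFrame, phen: pd.DataFrame | None, report: ValidationReport) -> None:
    required = {
        "subject_id", "gene", "variant_id", "hgvs_c", "consequence",
        "exon_index", "n_exons", "af_gnomad_nfe", "clinical_class",
    }
    if missing := required - set(var.columns):
        report.add("variants", f"missing columns {sorted(missing)}")
        return
    af = pd.to_numeric(var["af_gnomad_nfe"], errors="coerce")
    bad_af = var[(af < 0) | (af > 1)]
    if len(bad_af):
        report.add("variants", "af_gnomad_nfe outside [0, 1]", bad_af)
    bad_cons = var[~var["consequence"].isin(CONSEQUENCES)]
    if len(bad_cons):
        report.add("variants", "unknown consequence term", bad_cons)
    bad_class = var[~var["clinical_class"].isin(CLINICAL_CLASSES)]
    if len(bad_class):
        report.add("variants", "unknown clinical_class", bad_class)
    ei = pd.to_numeric(var["exon_index"], errors="coerce")
    ne = pd.to_numeric(var["n_exons"], errors="coerce")
    with np.errstate(invalid="ignore"):
        bad_exon = var[(ei.notna()) & (ne.notna()) & ((ei < 1) | (ei > ne))]
    if len(bad_exon):
        report.add("variants", "exon_index outside 1..n_exons", bad_exon)
    if phen is not None and "subject_id" in phen.columns:
        orphans = var[~var["subject_id"].astype(str).isin(phen["subject_id"].astype(str))]
        if len(orphans):
            report.add("variants", "subject_id not present in phenotype table", orphans)


def _check_domains(dom: pd.DataFrame, report: ValidationReport) -> None:
    from .classify import DomainMap

    try:
        DomainMap(dom)
    except ValueError as exc:
        report.add("domains", str(exc))


def _check_incidence(inc: pd.DataFrame, report: ValidationReport) -> None:
    from .risk import IncidenceTable

    try:
        IncidenceTable(inc)
    except ValueError as exc:
        report.add("incidence", str(exc))


def validate_frames(
    phenotypes: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
    domains: pd.DataFrame | None = None,
    incidence: pd.DataFrame | None = None,
) -> ValidationReport:
    report = ValidationReport()
    if phenotypes is not None:
        _check_phenotypes(phenotypes, report)
    if variants is not None:
        _check_variants(variants, phenotypes, report)
    if domains is not None:
        _check_domains(domains, report)
    if incidence is not None:
        _check_incidence(incidence, report)
    return report


def validate_inputs(paths: dict) -> ValidationReport:
    """Validate the input tables addressed by a path map with keys among
    {phenotypes, variants, domains, incidence}."""
    frames = {}
    report = ValidationReport()
    readers = {
        "phenotypes": lambda p: pd.read_csv(p),
        "variants": lambda p: pd.read_csv(p, sep="\t"),
        "domains": lambda p: pd.read_csv(p, sep="\t"),
        "incidence": lambda p: pd.read_csv(p),
    }
    for key, reader in readers.items():
        if key in paths and paths[key]:
            path = Path(paths[key])
            if not path.exists():
                report.add(key, f"file not found: {path}")
                continue
            frames[key] = reader(path)
    if report.errors:
        return report
    inner = validate_frames(
        phenotypes=frames.get("phenotypes"),
        variants=frames.get("variants"),
        domains=frames.get("domains"),
        incidence=frames.get("incidence"),
    )
    inner.errors = report.errors + inner.errors
    return inner
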