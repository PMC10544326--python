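"""Rule-based variant classification for panel-sequencing burden analysis.

Each annotated variant observation is mapped to exactly one of three
categories:

* ``PTV`` — protein-truncating: frameshift insertion/deletion, nonsense
  (stop-gain) or canonical +/-2 splice variant, excluding truncations in
  the last exon, splice variants affecting the penultimate exon (unless
  the gene is on the exception list where the truncated protein is still
  expected to be damaging), and a configurable set of named splice
  variants of uncertain clinical significance;
* ``RARE_MISSENSE`` — missense with gnomAD non-Finnish-European allele
  frequency below a threshold (default 0.001) and not classified
  (likely) benign;
* ``EXCLUDED`` — everything else, with an explicit machine-readable
  reason so filter attrition is auditable.

Consequence terms follow the ANNOVAR-style vocabulary; splice +/-2
membership is encoded by the upstream annotator in the consequence term
(this module never re-derives distances from genomic coordinates).
Retained missense variants are optionally annotated with the functional
protein domain containing their residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "ClassificationConfig",
    "ClassifiedVariant",
    "DomainMap",
    "classify_variant",
    "classify_table",
    "assign_domain",
    "assign_domains_table",
    "attrition_report",
    "CONSEQUENCES",
    "PTV_CONSEQUENCES",
    "SPLICE_CONSEQUENCES",
    "ESTABLISHED_GENES",
    "DEFAULT_PANEL_GENES",
    "EXCLUDED_BRCA1_SPLICE",
]

# ANNOVAR-style controlled vocabulary
PTV_CONSEQUENCES = frozenset(
    {"stopgain", "frameshift_insertion", "frameshift_deletion", "splicing"}
)
SPLICE_CONSEQUENCES = frozenset({"splicing"})
MISSENSE_CONSEQUENCES = frozenset({"nonsynonymous_SNV"})
OUT_OF_SCOPE_CONSEQUENCES = frozenset(
    {
        "nonframeshift_insertion",
        "nonframeshift_deletion",
        "synonymous_SNV",
        "intronic",
        "UTR5",
        "UTR3",
    }
)
CONSEQUENCES = PTV_CONSEQUENCES | MISSENSE_CONSEQUENCES | OUT_OF_SCOPE_CONSEQUENCES

# the nine genes with established evidence for breast-cancer susceptibility
ESTABLISHED_GENES = frozenset(
    {"ATM", "BARD1", "BRCA1", "BRCA2", "CHEK2", "PALB2", "RAD51C", "RAD51D", "TP53"}
)

# Representative 34-gene analyzed panel (PPM1D sequenced but excluded for
# somatic mosaicism).  Membership is configurable; this default covers all
# genes reported in the source cohort plus standard panel genes.
DEFAULT_PANEL_GENES = frozenset(
    {
        "ABRAXAS1", "AKT1", "ATM", "BABAM2", "BARD1", "BRCA1", "BRCA2", "BRIP1",
        "CDH1", "CHEK2", "EPCAM", "FANCC", "FANCM", "GEN1", "MEN1", "MLH1",
        "MRE11", "MSH2", "MSH6", "MUTYH", "NBN", "NF1", "PALB2", "PIK3CA",
        "PMS2", "PTEN", "RAD50", "RAD51C", "RAD51D", "RECQL", "RINT1", "STK11",
        "TP53", "XRCC2",
    }
)

# canonical BRCA1 splice variants of uncertain significance under expert-
# panel (ENIGMA-style) classification, removed from the PTV category
EXCLUDED_BRCA1_SPLICE = frozenset(
    {
        ("BRCA1", "c.594-2A>C"),
        ("BRCA1", "c.4096+1G>A"),
        ("BRCA1", "c.4096+2T>C"),
        ("BRCA1", "c.4186-2A>G"),
        ("BRCA1", "c.4358-1G>C"),
        ("BRCA1", "c.4358-2del"),
    }
)

CLINICAL_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "unclassified"}
)

EXCLUSION_REASONS = (
    "gene_excluded",
    "consequence_out_of_scope",
    "last_exon",
    "penultimate_splice",
    "uncertain_splice",
    "benign",
    "common",
)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant observation in one subject."""

    subject_id: str
    gene: str
    variant_id: str
    hgvs_c: str
    consequence: str
    exon_index: int | None = None
    n_exons: int | None = None
    af_gnomad_nfe: float | None = None
    clinical_class: str = "unclassified"
    protein_pos: int | None = None
    zygosity: str = "het"

    def __post_init__(self):
        if self.exon_index is not None and self.n_exons is not None:
            if not (1 <= self.exon_index <= self.n_exons):
                raise ValueError(
                    f"exon_index {self.exon_index} outside 1..{self.n_exons} "
                    f"for variant {self.variant_id}"
                )
        if self.af_gnomad_nfe is not None and not (0.0 <= self.af_gnomad_nfe <= 1.0):
            raise ValueError(f"allele frequency {self.af_gnomad_nfe} outside [0, 1]")


@dataclass(frozen=True)
class ClassificationConfig:
    """Configuration of the classification rules (defaults mirror the
    analysis conventions described in the module docstring)."""

    panel_genes: frozenset = DEFAULT_PANEL_GENES
    established_genes: frozenset = ESTABLISHED_GENES
    excluded_genes: frozenset = frozenset({"PPM1D"})
    penultimate_exception_genes: frozenset = frozenset(
        {"ATM", "BARD1", "BRCA1", "RAD51C", "RAD51D", "PALB2"}
    )
    excluded_splice_hgvs: frozenset = EXCLUDED_BRCA1_SPLICE
    missense_af_threshold: float = 0.001

    def __post_init__(self):
        if not (0.0 < self.missense_af_threshold < 1.0):
            raise ValueError("missense_af_threshold must be in (0, 1)")
        overlap = self.excluded_genes & self.panel_genes
        if overlap:
            raise ValueError(
                f"excluded_genes overlap the analyzed panel: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class ClassifiedVariant:
    """A VariantRecord plus its category, exclusion reason and domain."""

    record: VariantRecord
    category: str  # PTV | RARE_MISSENSE | EXCLUDED
    exclusion_reason: str | None = None
    domain: str | None = None
    af_unknown: bool = False

    def __post_init__(self):
        if (self.category == "EXCLUDED") != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason present iff category == EXCLUDED")


def classify_variant(v: VariantRecord, cfg: ClassificationConfig) -> ClassifiedVariant:
    """Apply the classification decision procedure to one variant.

    Rule order: excluded gene; out-of-scope consequence; the PTV rules
    (last exon, penultimate splice with gene exceptions, named uncertain
    splice variants); then the missense rules (benign removal, allele-
    frequency threshold).  Missense with unknown allele frequency is kept
    as rare but flagged ``af_unknown`` (absence from the reference
    population implies rarity).
    """
    if v.consequence not in CONSEQUENCES:
        raise ValueError(
            f"unknown consequence term {v.consequence!r}; expected one of "
            f"{sorted(CONSEQUENCES)}"
        )
    if v.gene in cfg.excluded_genes:
        return ClassifiedVariant(v, "EXCLUDED", "gene_excluded")
    if v.consequence in OUT_OF_SCOPE_CONSEQUENCES:
        return ClassifiedVariant(v, "EXCLUDED", "consequence_out_of_scope")
    if v.consequence in PTV_CONSEQUENCES:
        if v.exon_index is None or v.n_exons is None:
            raise ValueError(
                f"variant {v.variant_id}: exon_index/n_exons required for "
                f"truncating consequence {v.consequence!r}"
            )
        if v.exon_index == v.n_exons:
            return ClassifiedVariant(v, "EXCLUDED", "last_exon")
        if (
            v.consequence in SPLICE_CONSEQUENCES
            and v.exon_index == v.n_exons - 1
            and v.gene not in cfg.penultimate_exception_genes
        ):
            return ClassifiedVariant(v, "EXCLUDED", "penultimate_splice")
        if (v.gene, v.hgvs_c) in cfg.excluded_splice_hgvs:
            return ClassifiedVariant(v, "EXCLUDED", "uncertain_splice")
        return ClassifiedVariant(v, "PTV")
    # missense
    if v.clinical_class in {"benign", "likely_benign"}:
        return ClassifiedVariant(v, "EXCLUDED", "benign")
    if v.af_gnomad_nfe is not None and v.af_gnomad_nfe >= cfg.missense_af_threshold:
        return ClassifiedVariant(v, "EXCLUDED", "common")
    return ClassifiedVariant(v, "RARE_MISSENSE", af_unknown=v.af_gnomad_nfe is None)


def _record_from_row(row) -> VariantRecord:
    def _i(x):
        return None if pd.isna(x) else int(x)

    def _f(x):
        return None if pd.isna(x) else float(x)

    return VariantRecord(
        subject_id=str(row.subject_id),
        gene=str(row.gene),
        variant_id=str(row.variant_id),
        hgvs_c=str(row.hgvs_c),
        consequence=str(row.consequence),
        exon_index=_i(row.exon_index),
        n_exons=_i(row.n_exons),
        af_gnomad_nfe=_f(row.af_gnomad_nfe),
        clinical_class=str(row.clinical_class),
        protein_pos=_i(getattr(row, "protein_pos", np.nan)),
        zygosity=str(getattr(row, "zygosity", "het")),
    )


def classify_table(variants: pd.DataFrame, cfg: ClassificationConfig) -> pd.DataFrame:
    """Classify every row of a variant table.

    Returns a copy with ``category``, ``exclusion_reason``, ``domain`` and
    ``af_unknown`` columns appended.  Classification of a row depends only
    on that row and the configuration, so row order is irrelevant.
    """
    cats, reasons, flags = [], [], []
    for row in variants.itertuples(index=False):
        cv = classify_variant(_record_from_row(row), cfg)
        cats.append(cv.category)
        reasons.append(cv.exclusion_reason or "")
        flags.append(cv.af_unknown)
    out = variants.copy()
    out["category"] = cats
    out["exclusion_reason"] = reasons
    out["domain"] = ""
    out["af_unknown"] = flags
    return out


class DomainMap:
    """Gene -> named residue intervals (1-based, inclusive bounds).

    Intervals within a gene must not overlap; violated maps are rejected
    at construction time.
    """

    def __init__(self, entries: pd.DataFrame):
        required = {"gene", "domain", "residue_start", "residue_end"}
        missing = required - set(entries.columns)
        if missing:
            raise ValueError(f"domain map missing columns: {sorted(missing)}")
        df = entries.copy()
        df["residue_start"] = df["residue_start"].astype(int)
        df["residue_end"] = df["residue_end"].astype(int)
        bad = df[df["residue_start"] > df["residue_end"]]
        if len(bad):
            raise ValueError(
                f"domain intervals with start > end: {bad.to_dict('records')[:5]}"
            )
        for gene, grp in df.groupby("gene"):
            g = grp.sort_values("residue_start")
            starts = g["residue_start"].to_numpy()
            ends = g["residue_end"].to_numpy()
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(f"overlapping domain intervals in gene {gene}")
        self.entries = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "DomainMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def lookup(self, gene: str, protein_pos: int | None) -> str | None:
        """Name of the unique domain interval containing the residue."""
        if protein_pos is None:
            return None
        g = self.entries[self.entries["gene"] == gene]
        hit = g[(g["residue_start"] <= protein_pos) & (protein_pos <= g["residue_end"])]
        if len(hit) == 0:
            return None
        return str(hit.iloc[0]["domain"])


def assign_domain(cv: ClassifiedVariant, dm: DomainMap) -> ClassifiedVariant:
    """Annotate a rare missense variant with its protein domain (if any);
    PTVs and excluded variants pass through unchanged."""
    if cv.category != "RARE_MISSENSE":
        return cv
    return replace(cv, domain=dm.lookup(cv.record.gene, cv.record.protein_pos))


def assign_domains_table(classified: pd.DataFrame, dm: DomainMap) -> pd.DataFrame:
    out = classified.copy()
    mask = out["category"] == "RARE_MISSENSE"
    out.loc[mask, "domain"] = [
        dm.lookup(g, None if pd.isna(p) else int(p)) or ""
        for g, p in zip(out.loc[mask, "gene"], out.loc[mask, "protein_pos"])
    ]
    return out


def attrition_report(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-category and per-exclusion-reason row counts (filter attrition)."""
    rows = [
        {"item": f"category:{cat}", "rows": int((classified["category"] == cat).sum())}
        for cat in ("PTV", "RARE_MISSENSE", "EXCLUDED")
    ]
    excl = classified[classified["category"] == "EXCLUDED"]
    for reason in EXCLUSION_REASONS:
        rows.append(
            {"item": f"excluded:{reason}", "rows": int((excl["exclusion_reason"] == reason).sum())}
        )
    rows.append({"item": "total", "rows": int(len(classified))})
    return pd.DataFrame(rows)


def iter_records(variants: pd.DataFrame) -> Iterable[VariantRecord]:
    for row in variants.itertuples(index=False):
        yield _record_from_row(row)
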