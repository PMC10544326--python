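"""Carrier-burden tabulation and descriptive stratified comparisons.

Collapses classified variants to per-subject, per-gene (or per-domain)
binary carrier indicators — heterozygous and homozygous carriers, and
subjects with several qualifying variants in a unit, all count once —
then produces prevalence tables, gene-set aggregates, and the standard
descriptive stratifications of a case-control cohort: family history,
age at diagnosis dichotomized at 50 years, and tumor receptor subtype
(ER/PR/HER2, with triple-negative defined only for fully typed tumors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CarrierMatrix",
    "build_carrier_matrix",
    "tabulate_prevalence",
    "format_prevalence",
    "subtype_labels",
    "stratify",
    "compare_group_location",
    "compare_two_proportions",
]


@dataclass
class CarrierMatrix:
    """Subjects x units binary carrier indicators for one variant category.

    ``indicator`` is indexed by subject_id (all phenotyped subjects, in
    phenotype-table order) with one 0/1 column per unit (gene, or
    "gene:domain" label).  ``n_variants`` counts unique (gene, variant_id)
    keys per unit, pooled across cases and controls.
    """

    indicator: pd.DataFrame
    category: str
    unit_level: str
    n_variants: pd.Series

    @property
    def subjects(self) -> pd.Index:
        return self.indicator.index

    @property
    def units(self) -> list[str]:
        return list(self.indicator.columns)


def build_carrier_matrix(
    classified: pd.DataFrame,
    phenotypes: pd.DataFrame,
    category: str,
    unit_level: str = "gene",
) -> CarrierMatrix:
    """Binary subject x unit carrier matrix for one category.

    A subject carrying >= 1 qualifying variant in a unit gets indicator 1
    regardless of zygosity or multiplicity; subjects with no qualifying
    variants appear as all-zero rows.

    Raises
    ------
    ValueError : if the classified table references subject ids absent
        from the phenotype table, or unit_level is unknown.
    """
    if category not in {"PTV", "RARE_MISSENSE"}:
        raise ValueError(f"unknown category {category!r}")
    if unit_level not in {"gene", "domain"}:
        raise ValueError(f"unknown unit_level {unit_level!r}")
    subjects = pd.Index(phenotypes["subject_id"].astype(str), name="subject_id")
    rows = classified[classified["category"] == category].copy()
    rows["subject_id"] = rows["subject_id"].astype(str)
    orphans = sorted(set(rows["subject_id"]) - set(subjects))
    if orphans:
        raise ValueError(f"variant rows reference unknown subject ids: {orphans[:10]}")
    if unit_level == "gene":
        rows["unit"] = rows["gene"].astype(str)
    else:
        rows = rows[rows["domain"].astype(str) != ""]
        rows["unit"] = rows["gene"].astype(str) + ":" + rows["domain"].astype(str)
    units = sorted(rows["unit"].unique())
    ind = pd.DataFrame(0, index=subjects, columns=units, dtype=np.int8)
    if len(rows):
        flags = (
            rows.groupby(["subject_id", "unit"]).size().unstack(fill_value=0) > 0
        ).astype(np.int8)
        ind.loc[flags.index, flags.columns] = flags
    nvar = (
        rows.drop_duplicates(["unit", "gene", "variant_id"]).groupby("unit").size()
        if len(rows)
        else pd.Series(dtype=int)
    )
    nvar = nvar.reindex(units, fill_value=0).astype(int)
    return CarrierMatrix(indicator=ind, category=category, unit_level=unit_level, n_variants=nvar)


def _any_carrier(cm: CarrierMatrix, cols: Sequence[str]) -> pd.Series:
    present = [c for c in cols if c in cm.indicator.columns]
    if not present:
        return pd.Series(0, index=cm.subjects, dtype=np.int8)
    return (cm.indicator[present].sum(axis=1) > 0).astype(np.int8)


def tabulate_prevalence(
    cm: CarrierMatrix,
    phenotypes: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-unit (and per-gene-set) carrier counts and prevalences.

    Prevalence is 100 * carriers / group size; percentages are stored at
    full precision and rounded only at presentation.  A gene-set row
    counts each subject once even if they carry variants in several
    member genes.
    """
    status = phenotypes.set_index(phenotypes["subject_id"].astype(str))["status"]
    case_ids = status[status == "case"].index
    control_ids = status[status == "control"].index
    n_cases, n_controls = len(case_ids), len(control_ids)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both cases and controls must be non-empty")

    records = []

    def add_row(label: str, carrier: pd.Series, n_variants: int, kind: str) -> None:
        kc = int(carrier.loc[case_ids].sum())
        kk = int(carrier.loc[control_ids].sum())
        records.append(
            {
                "unit": label,
                "kind": kind,
                "n_variants": n_variants,
                "n_case_carriers": kc,
                "case_prevalence_pct": 100.0 * kc / n_cases,
                "n_control_carriers": kk,
                "control_prevalence_pct": 100.0 * kk / n_controls,
            }
        )

    for unit in cm.units:
        add_row(unit, cm.indicator[unit], int(cm.n_variants[unit]), "unit")
    for name, members in (gene_sets or {}).items():
        members = list(members)
        present = [m for m in members if m in cm.indicator.columns]
        add_row(name, _any_carrier(cm, members), int(cm.n_variants.reindex(present).fillna(0).sum()), "set")
    # overall row: any unit
    add_row("any", _any_carrier(cm, cm.units), int(cm.n_variants.sum()), "total")
    return pd.DataFrame(records)


def format_prevalence(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation copy with percentages rounded to ``decimals``."""
    out = table.copy()
    for col in ("case_prevalence_pct", "control_prevalence_pct"):
        out[col] = out[col].round(decimals)
    return out


def subtype_labels(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-case receptor flags with explicit missingness.

    Triple-negative is defined only when all of ER, PR and HER2 are
    observed; otherwise it is NA.  Controls get all-NA rows.
    """
    idx = pd.Index(phenotypes["subject_id"].astype(str), name="subject_id")
    out = pd.DataFrame(index=idx)
    is_case = (phenotypes["status"] == "case").to_numpy()
    for marker in ("er", "pr", "her2"):
        # "NA" strings round-trip through CSV as real NaN; treat both as missing
        v = phenotypes[marker].astype("string").fillna("NA").to_numpy()
        pos = pd.array(v == "pos", dtype="boolean")
        neg = pd.array(v == "neg", dtype="boolean")
        observed = pd.array((v == "pos") | (v == "neg"), dtype="boolean") & is_case
        out[f"{marker}_pos"] = pos.copy()
        out[f"{marker}_neg"] = neg.copy()
        out.loc[~np.asarray(observed, dtype=bool), [f"{marker}_pos", f"{marker}_neg"]] = pd.NA
    fully = (
        out[["er_pos", "pr_pos", "her2_pos"]].notna().all(axis=1)
    )
    tn = pd.array([pd.NA] * len(out), dtype="boolean")
    tn[np.asarray(fully)] = (
        out.loc[fully, "er_neg"] & out.loc[fully, "pr_neg"] & out.loc[fully, "her2_neg"]
    ).to_numpy(dtype=bool)
    out["triple_negative"] = tn
    return out


def stratify(
    phenotypes: pd.DataFrame,
    by: str,
    age_cut: float = 50.0,
) -> tuple[dict[str, pd.Index], pd.Index]:
    """Partition subject ids by a stratifier.

    ``by`` is one of ``family_history``, ``age_cut`` (boundary: "<cut"
    vs ">=cut"), or ``subtype`` (cases only; ER+/ER-/triple-negative).
    Returns (partitions, dropped) where ``dropped`` holds subjects with
    the stratifier missing; partitions are disjoint.
    """
    ids = pd.Index(phenotypes["subject_id"].astype(str), name="subject_id")
    if by == "family_history":
        fh = pd.to_numeric(phenotypes["family_history"], errors="coerce")
        parts = {
            "fh_yes": ids[(fh == 1).to_numpy()],
            "fh_no": ids[(fh == 0).to_numpy()],
        }
        dropped = ids[fh.isna().to_numpy()]
    elif by == "age_cut":
        age = pd.to_numeric(phenotypes["age_years"], errors="coerce")
        parts = {
            f"age_lt{age_cut:g}": ids[(age < age_cut).to_numpy()],
            f"age_ge{age_cut:g}": ids[(age >= age_cut).to_numpy()],
        }
        dropped = ids[age.isna().to_numpy()]
    elif by == "subtype":
        labels = subtype_labels(phenotypes)
        is_case = (phenotypes["status"] == "case").to_numpy()
        er_pos = labels["er_pos"].fillna(False).to_numpy(dtype=bool) & is_case
        er_neg = labels["er_neg"].fillna(False).to_numpy(dtype=bool) & is_case
        tn = labels["triple_negative"].fillna(False).to_numpy(dtype=bool) & is_case
        parts = {
            "er_pos": ids[er_pos],
            "er_neg": ids[er_neg],
            "triple_negative": ids[tn],
        }
        dropped = ids[is_case & ~(er_pos | er_neg)]
    else:
        raise ValueError(f"unknown stratifier {by!r}")
    return parts, dropped


def compare_group_location(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "rank_sum",
) -> dict:
    """Two-sided location comparison of two samples (e.g. ages at
    diagnosis of carrier vs non-carrier cases).

    ``rank_sum`` is the Wilcoxon rank-sum (Mann-Whitney U) test with the
    normal approximation and tie correction for larger samples and the
    exact null distribution when both samples are small and untied;
    ``t_test`` is the classic equal-variance two-sample t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    summary = {
        "mean_x": float(np.mean(x)),
        "sd_x": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
        "mean_y": float(np.mean(y)),
        "sd_y": float(np.std(y, ddof=1)) if len(y) > 1 else float("nan"),
        "n_x": int(len(x)),
        "n_y": int(len(y)),
    }
    if method == "rank_sum":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "t_test":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test requires at least 2 observations per group")
        res = stats.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"method": method, "statistic": stat, "p": min(p, 1.0), **summary}


def compare_two_proportions(
    k1: int, n1: int, k2: int, n2: int, method: str = "fisher"
) -> float:
    """Two-sided p for H0: equal proportions.

    Default is Fisher's exact (conditional hypergeometric) test; a
    chi-square test with continuity correction is available via
    ``method="chi2"``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n):
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        return float(stats.chi2_contingency(table, correction=True)[1])
    raise ValueError(f"unknown method {method!r}")
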