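"""Published summary counts of the MASTOS breast-cancer case-control
cohort (Cyprus; 990 cases, 1,094 controls) and a synthetic subject-level
reconstruction of them.

The study's individual-level data are access-controlled, but its printed
per-gene carrier counts, family-history margins and receptor-subtype
margins determine the descriptive statistics exactly.
:func:`build_reference_cohort` lays out a synthetic subject-level dataset
(synthetic: subject identities and joint assignments are arbitrary)
whose marginal counts equal the published ones, so prevalence,
stratification and unadjusted 2x2 association code can be exercised
against the published numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burden import CarrierMatrix

__all__ = [
    "N_CASES",
    "N_CONTROLS",
    "ESTABLISHED_SET",
    "PTV_CASE_CARRIERS",
    "PTV_CONTROL_CARRIERS",
    "build_reference_cohort",
]

N_CASES = 990
N_CONTROLS = 1094

ESTABLISHED_SET = (
    "ATM", "BARD1", "BRCA1", "BRCA2", "CHEK2", "PALB2", "RAD51C", "RAD51D", "TP53",
)

# per-gene PTV carrier counts among cases / controls
PTV_CASE_CARRIERS = {
    "ATM": 9, "BRCA1": 3, "BRCA2": 18, "PALB2": 5,
    "ABRAXAS1": 1, "FANCC": 3, "MUTYH": 1, "RAD50": 4, "RECQL": 1,
}
PTV_CONTROL_CARRIERS = {
    "ATM": 1, "BRCA1": 1, "BRCA2": 1, "CHEK2": 1,
    "CDH1": 1, "FANCC": 2, "FANCM": 1, "GEN1": 1, "MRE11": 1,
    "MUTYH": 1, "RAD50": 1, "RECQL": 3, "RINT1": 1,
}
# unique PTVs per gene pooled over cases and controls
PTV_UNIQUE_VARIANTS = {
    "ATM": 7, "BRCA1": 1, "BRCA2": 6, "CHEK2": 1, "PALB2": 1,
    "ABRAXAS1": 1, "CDH1": 1, "FANCC": 2, "FANCM": 1, "GEN1": 1,
    "MRE11": 1, "MUTYH": 2, "RAD50": 1, "RECQL": 2, "RINT1": 1,
}

# founder BRCA2 frameshift (c.8756delG) carriers
FOUNDER_BRCA2_CASES = 10
FOUNDER_BRCA2_CONTROLS = 1

# family history of breast cancer (first-degree relatives): yes / no / missing
FH_CASES = (158, 815, 17)
FH_CONTROLS = (87, 1004, 3)
# PTV carriers among FH-yes / FH-no / FH-missing cases
FH_CASE_CARRIERS = (13, 29, 3)

# receptor-subtype structure among the 576 fully typed case tumors
FULLY_TYPED_CASES = 576
TRIPLE_NEGATIVE_CASES = 66
ER_POS_TYPED = 441
PR_POS_TYPED = 362
HER2_POS_TYPED = 93

# rare-missense carrier counts: (cases, controls)
MISSENSE_ESTABLISHED_CARRIERS = (195, 188)
MISSENSE_ANY_CARRIERS = (499, 457)

# mean +/- sd ages printed for the cohort
AGE_CASES = (51.5, 9.3)
AGE_CONTROLS = (55.7, 6.9)


def _assign_receptors(n_cases: int) -> pd.DataFrame:
    """Receptor columns for cases: the first FULLY_TYPED_CASES rows are
    fully typed with the published joint margins (66 TN, 441 ER+,
    362 PR+, 93 HER2+); the rest are untyped (NA)."""
    er = np.array(["NA"] * n_cases, dtype=object)
    pr = np.array(["NA"] * n_cases, dtype=object)
    her2 = np.array(["NA"] * n_cases, dtype=object)
    t = FULLY_TYPED_CASES
    # rows 0..65: triple negative
    er[:TRIPLE_NEGATIVE_CASES] = "neg"
    pr[:TRIPLE_NEGATIVE_CASES] = "neg"
    her2[:TRIPLE_NEGATIVE_CASES] = "neg"
    # rows 66..506: ER-positive block (441 rows)
    er_pos_stop = TRIPLE_NEGATIVE_CASES + ER_POS_TYPED
    er[TRIPLE_NEGATIVE_CASES:er_pos_stop] = "pos"
    # remaining typed rows: ER-negative but not TN (HER2+ to break TN)
    er[er_pos_stop:t] = "neg"
    her2[er_pos_stop:t] = "pos"
    pr[er_pos_stop:t] = "neg"
    # PR+ among typed: all inside the ER+ block
    pr[TRIPLE_NEGATIVE_CASES:TRIPLE_NEGATIVE_CASES + PR_POS_TYPED] = "pos"
    pr[TRIPLE_NEGATIVE_CASES + PR_POS_TYPED:er_pos_stop] = "neg"
    # HER2 among the ER+ block: enough positives to reach the margin
    her2_needed = HER2_POS_TYPED - (t - er_pos_stop)
    her2[TRIPLE_NEGATIVE_CASES:TRIPLE_NEGATIVE_CASES + her2_needed] = "pos"
    her2[TRIPLE_NEGATIVE_CASES + her2_needed:er_pos_stop] = "neg"
    return pd.DataFrame({"er": er, "pr": pr, "her2": her2})


def build_reference_cohort() -> tuple[pd.DataFrame, CarrierMatrix, CarrierMatrix]:
    """Synthetic subject-level reconstruction of the published margins.

    Returns (phenotypes, ptv_carriers, missense_carriers).  Carrier
    assignments are disjoint across genes (the published per-gene counts
    sum to the published set-level carrier totals, so no multi-gene
    carriers are needed).  Family-history labels are laid out so the
    carrier x family-history margin matches the published stratified
    counts.
    """
    case_ids = [f"case_{i + 1:05d}" for i in range(N_CASES)]
    ctrl_ids = [f"ctrl_{i + 1:05d}" for i in range(N_CONTROLS)]
    genes = sorted(set(PTV_CASE_CARRIERS) | set(PTV_CONTROL_CARRIERS))

    ptv = pd.DataFrame(0, index=pd.Index(case_ids + ctrl_ids, name="subject_id"),
                       columns=genes, dtype=np.int8)
    pos = 0
    for gene in genes:  # cases first, packed from the top
        k = PTV_CASE_CARRIERS.get(gene, 0)
        ptv.iloc[pos:pos + k, ptv.columns.get_loc(gene)] = 1
        pos += k
    n_case_carriers = pos
    pos = N_CASES
    for gene in genes:
        k = PTV_CONTROL_CARRIERS.get(gene, 0)
        ptv.iloc[pos:pos + k, ptv.columns.get_loc(gene)] = 1
        pos += k

    nvar = pd.Series(PTV_UNIQUE_VARIANTS).reindex(genes).fillna(0).astype(int)
    ptv_cm = CarrierMatrix(indicator=ptv, category="PTV", unit_level="gene",
                           n_variants=nvar)

    # family history: carriers occupy the head of the case list, so give
    # the first FH_CASE_CARRIERS[0] carriers FH=yes, the next block FH=no,
    # the last carriers FH=missing, and fill the remaining quotas with
    # non-carriers.
    fh = np.full(N_CASES + N_CONTROLS, np.nan)
    yes_c, no_c, na_c = FH_CASE_CARRIERS
    fh[:yes_c] = 1.0
    fh[yes_c:yes_c + no_c] = 0.0
    # the remaining carriers (indices yes_c+no_c .. n_case_carriers) stay NaN
    rest = list(range(n_case_carriers, N_CASES))
    n_yes_rest = FH_CASES[0] - yes_c
    n_no_rest = FH_CASES[1] - no_c
    fh[rest[:n_yes_rest]] = 1.0
    fh[rest[n_yes_rest:n_yes_rest + n_no_rest]] = 0.0
    assert na_c == n_case_carriers - yes_c - no_c
    ctrl_fh = np.concatenate(
        [
            np.ones(FH_CONTROLS[0]),
            np.zeros(FH_CONTROLS[1]),
            np.full(FH_CONTROLS[2], np.nan),
        ]
    )
    fh[N_CASES:] = ctrl_fh

    receptors_cases = _assign_receptors(N_CASES)
    phen = pd.DataFrame(
        {
            "subject_id": case_ids + ctrl_ids,
            "status": ["case"] * N_CASES + ["control"] * N_CONTROLS,
            "age_years": np.concatenate(
                [np.full(N_CASES, AGE_CASES[0]), np.full(N_CONTROLS, AGE_CONTROLS[0])]
            ),
            "family_history": fh,
            "er": list(receptors_cases["er"]) + ["NA"] * N_CONTROLS,
            "pr": list(receptors_cases["pr"]) + ["NA"] * N_CONTROLS,
            "her2": list(receptors_cases["her2"]) + ["NA"] * N_CONTROLS,
        }
    )

    # rare-missense carriers: established-gene carriers first (booked to
    # BRCA1), the remainder booked to a non-established gene (FANCM)
    mis = pd.DataFrame(0, index=ptv.index, columns=["BRCA1", "FANCM"], dtype=np.int8)
    est_cases, est_ctrls = MISSENSE_ESTABLISHED_CARRIERS
    any_cases, any_ctrls = MISSENSE_ANY_CARRIERS
    mis.iloc[:est_cases, 0] = 1
    mis.iloc[est_cases:any_cases, 1] = 1
    mis.iloc[N_CASES:N_CASES + est_ctrls, 0] = 1
    mis.iloc[N_CASES + est_ctrls:N_CASES + any_ctrls, 1] = 1
    mis_cm = CarrierMatrix(
        indicator=mis, category="RARE_MISSENSE", unit_level="gene",
        n_variants=pd.Series({"BRCA1": 147, "FANCM": 233}),
    )
    return phen, ptv_cm, mis_cm


def founder_breakdown() -> dict:
    """BRCA2 founder-variant prevalence among cases and its share of
    BRCA2 case carriers, from the published counts."""
    return {
        "founder_case_prevalence_pct": 100.0 * FOUNDER_BRCA2_CASES / N_CASES,
        "founder_share_of_brca2_case_carriers_pct": 100.0
        * FOUNDER_BRCA2_CASES
        / PTV_CASE_CARRIERS["BRCA2"],
        "founder_control_prevalence_pct": 100.0 * FOUNDER_BRCA2_CONTROLS / N_CONTROLS,
    }
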