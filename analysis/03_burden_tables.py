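#!/usr/bin/env python
"""Carrier-burden tabulation: per-gene PTV and rare-missense prevalence
with the established-gene aggregate, family-history and age strata, and
the descriptive group comparisons (carrier ages, family-history carrier
contrast).

Reads results/synthetic/ and results/classified.tsv; writes
results/prevalence_{ptv,missense}.tsv and prints the stratified
summaries.
"""

from pathlib import Path

import pandas as pd

from panelburden.burden import (
    build_carrier_matrix,
    compare_group_location,
    compare_two_proportions,
    format_prevalence,
    stratify,
    tabulate_prevalence,
)
from panelburden.classify import ESTABLISHED_GENES

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    phen = pd.read_csv(ROOT / "synthetic" / "phenotypes.csv")
    classified = pd.read_csv(ROOT / "classified.tsv", sep="\t")
    gene_sets = {"established": sorted(ESTABLISHED_GENES)}

    for category, fname in (("PTV", "prevalence_ptv.tsv"),
                            ("RARE_MISSENSE", "prevalence_missense.tsv")):
        cm = build_carrier_matrix(classified, phen, category)
        table = format_prevalence(tabulate_prevalence(cm, phen, gene_sets))
        table.to_csv(ROOT / fname, sep="\t", index=False)
        print(f"\n{category} prevalence:")
        print(table.to_string(index=False))

    # family-history stratified PTV prevalence among cases
    cm = build_carrier_matrix(classified, phen, "PTV")
    cases = phen[phen["status"] == "case"]
    parts, dropped = stratify(cases, "family_history")
    any_carrier = cm.indicator.sum(axis=1) > 0
    k_fh = int(any_carrier.loc[parts["fh_yes"]].sum())
    k_no = int(any_carrier.loc[parts["fh_no"]].sum())
    p = compare_two_proportions(k_fh, len(parts["fh_yes"]), k_no, len(parts["fh_no"]))
    print(f"\nPTV carriers among FH+ cases: {k_fh}/{len(parts['fh_yes'])}"
          f" vs FH- cases: {k_no}/{len(parts['fh_no'])} (p = {p:.3f};"
          f" {len(dropped)} cases missing FH)")

    # carrier vs non-carrier age at diagnosis (BRCA-gene carriers)
    brca_cols = [c for c in cm.indicator.columns if c in ("BRCA1", "BRCA2")]
    if brca_cols:
        brca = cm.indicator[brca_cols].sum(axis=1) > 0
        case_ids = cases["subject_id"]
        ages = cases.set_index("subject_id")["age_years"]
        x = ages[brca.loc[case_ids].to_numpy()]
        y = ages[~brca.loc[case_ids].to_numpy()]
        if len(x) >= 2:
            res = compare_group_location(x, y, method="rank_sum")
            print(f"BRCA1/2 carrier case ages: {res['mean_x']:.1f}±{res['sd_x']:.1f}"
                  f" vs non-carrier {res['mean_y']:.1f}±{res['sd_y']:.1f}"
                  f" (rank-sum p = {res['p']:.3f})")


if __name__ == "__main__":
    main()
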