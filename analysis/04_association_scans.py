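#!/usr/bin/env python
"""Firth association scans: per-gene PTV and rare-missense odds ratios
(adjusted for age and family history) for overall, ER+, ER- and
triple-negative disease; domain-level missense scan; carrier-by-age
interaction for genes with enough carriers.

Reads results/synthetic/ and results/classified.tsv; writes
results/associations.tsv and results/age_trends.tsv.
"""

import warnings
from pathlib import Path

import pandas as pd

from panelburden.burden import build_carrier_matrix
from panelburden.classify import ESTABLISHED_GENES
from panelburden.firth import DesignSpec, OUTCOMES, association_scan, fit_age_trend, results_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    phen = pd.read_csv(ROOT / "synthetic" / "phenotypes.csv")
    classified = pd.read_csv(ROOT / "classified.tsv", sep="\t")

    frames = []
    for category in ("PTV", "RARE_MISSENSE"):
        cm = build_carrier_matrix(classified, phen, category)
        specs = [DesignSpec(outcome=o) for o in OUTCOMES]
        res = results_frame(association_scan(cm, phen, specs))
        res["category"] = category
        res["unit_level"] = "gene"
        frames.append(res)
    cmd = build_carrier_matrix(
        classified[classified["gene"].isin(ESTABLISHED_GENES)], phen,
        "RARE_MISSENSE", "domain",
    )
    if cmd.units:
        res = results_frame(association_scan(cmd, phen, [DesignSpec(outcome="overall")]))
        res["category"] = "RARE_MISSENSE"
        res["unit_level"] = "domain"
        frames.append(res)
    assoc = pd.concat(frames, ignore_index=True)
    assoc.to_csv(ROOT / "associations.tsv", sep="\t", index=False)

    overall = assoc[(assoc["outcome"] == "overall") & (assoc["unit_level"] == "gene")
                    & (assoc["category"] == "PTV")]
    print("PTV associations with overall disease (age- and FH-adjusted):")
    for _, r in overall.sort_values("or_hat", ascending=False).iterrows():
        print(f"  {r['unit']:<8} OR {r['or_hat']:6.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
              f"  p = {r['p_wald']:.4f}  carriers {r['n_case_carriers']}/{r['n_control_carriers']}")

    cm = build_carrier_matrix(classified, phen, "PTV")
    trends = []
    for unit in cm.units:
        if cm.indicator[unit].sum() >= 5:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tr = fit_age_trend(cm, phen, unit)
            trends.append({"unit": unit, "multiplier": tr.multiplier,
                           "ci_low": tr.ci_low, "ci_high": tr.ci_high, "p": tr.p})
    tdf = pd.DataFrame(trends)
    tdf.to_csv(ROOT / "age_trends.tsv", sep="\t", index=False)
    if len(tdf):
        print("\nPer-year OR multipliers (carrier x age interaction):")
        print(tdf.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
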