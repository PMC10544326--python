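#!/usr/bin/env python
"""Classify every variant row of the synthetic cohort into PTV /
rare-missense / excluded (with reason), annotate rare missense variants
with protein domains, and report the filter attrition.

Reads results/synthetic/, writes results/classified.tsv and
results/attrition.tsv.
"""

from pathlib import Path

import pandas as pd

from panelburden.classify import (
    ClassificationConfig,
    DomainMap,
    assign_domains_table,
    attrition_report,
    classify_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    variants = pd.read_csv(ROOT / "synthetic" / "variants.tsv", sep="\t")
    dm = DomainMap.from_tsv(ROOT / "synthetic" / "domains.tsv")
    classified = assign_domains_table(
        classify_table(variants, ClassificationConfig()), dm
    )
    classified.to_csv(ROOT / "classified.tsv", sep="\t", index=False)
    att = attrition_report(classified)
    att.to_csv(ROOT / "attrition.tsv", sep="\t", index=False)
    print(att.to_string(index=False))


if __name__ == "__main__":
    main()
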