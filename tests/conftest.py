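"""Shared fixtures: classification config, domain map, and a randomized
variant-table fixture that exercises every classification rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelburden.classify import ClassificationConfig, EXCLUDED_BRCA1_SPLICE
from panelburden.simulate import default_domain_map


@pytest.fixture(scope="session")
def clf_cfg() -> ClassificationConfig:
    return ClassificationConfig()


@pytest.fixture(scope="session")
def domain_map():
    return default_domain_map()


def make_rule_fixture(n_rows: int = 200, seed: int = 314) -> pd.DataFrame:
    """Randomized variant table in which every classification rule fires:
    qualifying PTVs, last-exon PTVs, penultimate splice in exception and
    non-exception genes, the named uncertain BRCA1 splice variants, rare /
    common / benign missense, AF exactly at the threshold, in-frame
    indels, UTR/intronic/synonymous rows and PPM1D rows."""
    rng = np.random.default_rng(seed)
    genes = ["ATM", "BRCA1", "BRCA2", "CHEK2", "PALB2", "FANCC", "RAD50", "MUTYH"]
    n_exons = {"ATM": 63, "BRCA1": 23, "BRCA2": 27, "CHEK2": 15, "PALB2": 13,
               "FANCC": 15, "RAD50": 25, "MUTYH": 16}
    brca1_splice = sorted(h for _, h in EXCLUDED_BRCA1_SPLICE)
    rows = []
    kinds = [
        "ptv", "ptv", "last_exon", "pen_splice_exc", "pen_splice_nonexc",
        "brca1_named", "rare_mis", "rare_mis", "common_mis", "boundary_mis",
        "benign_mis", "unknown_af_mis", "inframe", "utr", "intronic",
        "synonymous", "ppm1d",
    ]
    for i in range(n_rows):
        kind = kinds[i % len(kinds)]
        gene = genes[int(rng.integers(len(genes)))]
        nex = n_exons[gene]
        row = {
            "subject_id": f"s{int(rng.integers(500)):04d}",
            "gene": gene,
            "variant_id": f"v{i:04d}",
            "hgvs_c": f"c.{int(rng.integers(100, 8000))}G>A",
            "consequence": "nonsynonymous_SNV",
            "exon_index": int(rng.integers(1, nex + 1)),
            "n_exons": nex,
            "af_gnomad_nfe": float(rng.random() * 9e-4),
            "clinical_class": "vus",
            "protein_pos": int(rng.integers(1, 1000)),
            "zygosity": "het",
        }
        if kind == "ptv":
            row.update(consequence=str(rng.choice(["stopgain", "frameshift_deletion",
                                                   "frameshift_insertion"])),
                       exon_index=int(rng.integers(1, nex)))
        elif kind == "last_exon":
            row.update(consequence=str(rng.choice(["stopgain", "frameshift_deletion",
                                                   "splicing"])),
                       exon_index=nex)
        elif kind == "pen_splice_exc":
            gene = str(rng.choice(["ATM", "BRCA1", "PALB2"]))
            nex = n_exons[gene]
            row.update(gene=gene, n_exons=nex, consequence="splicing", exon_index=nex - 1)
        elif kind == "pen_splice_nonexc":
            gene = str(rng.choice(["CHEK2", "FANCC", "RAD50"]))
            nex = n_exons[gene]
            row.update(gene=gene, n_exons=nex, consequence="splicing", exon_index=nex - 1)
        elif kind == "brca1_named":
            nex = n_exons["BRCA1"]
            row.update(gene="BRCA1", n_exons=nex, consequence="splicing",
                       exon_index=int(rng.integers(1, nex - 1)),
                       hgvs_c=str(rng.choice(brca1_splice)))
        elif kind == "common_mis":
            row.update(af_gnomad_nfe=float(0.001 + rng.random() * 0.01))
        elif kind == "boundary_mis":
            row.update(af_gnomad_nfe=0.001)  # exactly at threshold: excluded
        elif kind == "benign_mis":
            row.update(clinical_class=str(rng.choice(["benign", "likely_benign"])))
        elif kind == "unknown_af_mis":
            row.update(af_gnomad_nfe=np.nan)
        elif kind == "inframe":
            row.update(consequence=str(rng.choice(["nonframeshift_insertion",
                                                   "nonframeshift_deletion"])))
        elif kind == "utr":
            row.update(consequence=str(rng.choice(["UTR5", "UTR3"])))
        elif kind == "intronic":
            row.update(consequence="intronic")
        elif kind == "synonymous":
            row.update(consequence="synonymous_SNV")
        elif kind == "ppm1d":
            row.update(gene="PPM1D", n_exons=6, exon_index=3, consequence="stopgain")
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rule_fixture() -> pd.DataFrame:
    return make_rule_fixture()


def oracle_classify_row(row, cfg: ClassificationConfig) -> tuple[str, str]:
    """Independent straight-line re-implementation of the rule list, kept
    deliberately naive (no shared code with the package path)."""
    gene = row["gene"]
    cons = row["consequence"]
    if gene in cfg.excluded_genes:
        return "EXCLUDED", "gene_excluded"
    if cons in {"nonframeshift_insertion", "nonframeshift_deletion",
                "synonymous_SNV", "intronic", "UTR5", "UTR3"}:
        return "EXCLUDED", "consequence_out_of_scope"
    if cons in {"stopgain", "frameshift_insertion", "frameshift_deletion", "splicing"}:
        if int(row["exon_index"]) == int(row["n_exons"]):
            return "EXCLUDED", "last_exon"
        if (
            cons == "splicing"
            and int(row["exon_index"]) == int(row["n_exons"]) - 1
            and gene not in cfg.penultimate_exception_genes
        ):
            return "EXCLUDED", "penultimate_splice"
        if (gene, row["hgvs_c"]) in cfg.excluded_splice_hgvs:
            return "EXCLUDED", "uncertain_splice"
        return "PTV", ""
    if row["clinical_class"] in ("benign", "likely_benign"):
        return "EXCLUDED", "benign"
    af = row["af_gnomad_nfe"]
    if af == af and af is not None and float(af) >= cfg.missense_af_threshold:
        return "EXCLUDED", "common"
    return "RARE_MISSENSE", ""
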