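"""Variant classification rules, domain assignment, and agreement with an
independently coded rule oracle."""

from __future__ import annotations

import pandas as pd
import pytest

from panelburden.classify import (
    ClassificationConfig,
    DomainMap,
    VariantRecord,
    assign_domain,
    assign_domains_table,
    attrition_report,
    classify_table,
    classify_variant,
)

from conftest import make_rule_fixture, oracle_classify_row


def rec(**kw) -> VariantRecord:
    base = dict(
        subject_id="s1", gene="CHEK2", variant_id="v1", hgvs_c="c.100G>A",
        consequence="nonsynonymous_SNV", exon_index=3, n_exons=15,
        af_gnomad_nfe=0.0005, clinical_class="vus", protein_pos=100,
    )
    base.update(kw)
    return VariantRecord(**base)


class TestRules:
    @pytest.mark.parametrize(
        "kw,category,reason",
        [
            # named uncertain BRCA1 splice variants are pulled out of PTV
            (dict(gene="BRCA1", hgvs_c="c.594-2A>C", consequence="splicing",
                  exon_index=9, n_exons=23), "EXCLUDED", "uncertain_splice"),
            # penultimate-exon splice in an exception gene is kept as PTV
            (dict(gene="PALB2", consequence="splicing", exon_index=12, n_exons=13),
             "PTV", None),
            # ... but excluded in a non-exception gene
            (dict(gene="CHEK2", consequence="splicing", exon_index=14, n_exons=15),
             "EXCLUDED", "penultimate_splice"),
            # rare missense kept; at/above the frequency threshold excluded
            (dict(af_gnomad_nfe=0.0005), "RARE_MISSENSE", None),
            (dict(af_gnomad_nfe=0.002), "EXCLUDED", "common"),
            (dict(af_gnomad_nfe=0.001), "EXCLUDED", "common"),  # boundary: >= threshold
            # truncations in the last exon are excluded
            (dict(consequence="stopgain", exon_index=15, n_exons=15),
             "EXCLUDED", "last_exon"),
            (dict(consequence="stopgain", exon_index=3), "PTV", None),
            # a nonsense variant in the penultimate exon is a PTV (the
            # penultimate rule is splice-specific)
            (dict(consequence="stopgain", exon_index=14, n_exons=15), "PTV", None),
            (dict(gene="PPM1D", consequence="stopgain", exon_index=2, n_exons=6),
             "EXCLUDED", "gene_excluded"),
            (dict(consequence="nonframeshift_insertion"), "EXCLUDED",
             "consequence_out_of_scope"),
            (dict(consequence="UTR5"), "EXCLUDED", "consequence_out_of_scope"),
            (dict(consequence="intronic"), "EXCLUDED", "consequence_out_of_scope"),
            (dict(clinical_class="likely_benign"), "EXCLUDED", "benign"),
            (dict(clinical_class="benign", af_gnomad_nfe=0.005), "EXCLUDED", "benign"),
        ],
    )
    def test_rule_outcomes(self, clf_cfg, kw, category, reason):
        cv = classify_variant(rec(**kw), clf_cfg)
        assert cv.category == category
        assert cv.exclusion_reason == reason

    def test_all_six_brca1_splice_names_excluded(self, clf_cfg):
        for gene, hgvs in sorted(clf_cfg.excluded_splice_hgvs):
            cv = classify_variant(
                rec(gene=gene, hgvs_c=hgvs, consequence="splicing",
                    exon_index=5, n_exons=23),
                clf_cfg,
            )
            assert cv.category == "EXCLUDED" and cv.exclusion_reason == "uncertain_splice"

    def test_unknown_consequence_is_an_error(self, clf_cfg):
        with pytest.raises(ValueError, match="stop_lost"):
            classify_variant(rec(consequence="stop_lost"), clf_cfg)

    def test_missing_exon_index_for_truncating_variant(self, clf_cfg):
        with pytest.raises(ValueError, match="exon_index"):
            classify_variant(
                rec(consequence="stopgain", exon_index=None, n_exons=None), clf_cfg
            )

    def test_unknown_af_missense_kept_but_flagged(self, clf_cfg):
        cv = classify_variant(rec(af_gnomad_nfe=None), clf_cfg)
        assert cv.category == "RARE_MISSENSE"
        assert cv.af_unknown

    def test_pathogenic_missense_retained_in_rare_missense(self, clf_cfg):
        cv = classify_variant(rec(clinical_class="pathogenic"), clf_cfg)
        assert cv.category == "RARE_MISSENSE"

    def test_penultimate_exception_set_is_configurable(self):
        cfg = ClassificationConfig(penultimate_exception_genes=frozenset({"CHEK2"}))
        cv = classify_variant(
            rec(gene="CHEK2", consequence="splicing", exon_index=14, n_exons=15), cfg
        )
        assert cv.category == "PTV"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            ClassificationConfig(missense_af_threshold=0.0)
        with pytest.raises(ValueError, match="overlap"):
            ClassificationConfig(excluded_genes=frozenset({"BRCA1"}))


class TestOracleAgreement:
    def test_200_row_fixture_matches_independent_oracle(self, clf_cfg, rule_fixture):
        classified = classify_table(rule_fixture, clf_cfg)
        for i, row in classified.iterrows():
            cat, reason = oracle_classify_row(row, clf_cfg)
            assert (row["category"], row["exclusion_reason"]) == (cat, reason), (
                f"row {i}: {row.to_dict()}"
            )

    def test_partition_and_counts(self, clf_cfg, rule_fixture):
        classified = classify_table(rule_fixture, clf_cfg)
        counts = classified["category"].value_counts()
        assert counts.sum() == len(rule_fixture)
        assert set(counts.index) <= {"PTV", "RARE_MISSENSE", "EXCLUDED"}
        report = attrition_report(classified)
        total = report.loc[report["item"] == "total", "rows"].iloc[0]
        assert total == len(rule_fixture)
        cat_rows = report[report["item"].str.startswith("category:")]["rows"].sum()
        assert cat_rows == len(rule_fixture)

    def test_order_independence(self, clf_cfg, rule_fixture):
        shuffled = rule_fixture.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = classify_table(rule_fixture, clf_cfg).set_index("variant_id")
        b = classify_table(shuffled, clf_cfg).set_index("variant_id")
        b = b.loc[a.index]
        assert (a["category"] == b["category"]).all()
        assert (a["exclusion_reason"] == b["exclusion_reason"]).all()

    def test_every_rule_fires_in_fixture(self, clf_cfg):
        classified = classify_table(make_rule_fixture(200, seed=7), clf_cfg)
        reasons = set(classified.loc[classified["category"] == "EXCLUDED",
                                     "exclusion_reason"])
        assert reasons == {
            "gene_excluded", "consequence_out_of_scope", "last_exon",
            "penultimate_splice", "uncertain_splice", "benign", "common",
        }
        assert (classified["category"] == "PTV").any()
        assert (classified["category"] == "RARE_MISSENSE").any()


class TestDomainAssignment:
    def test_residue_inside_interval(self, clf_cfg, domain_map):
        cv = classify_variant(rec(gene="PALB2", protein_pos=860), clf_cfg)
        assert assign_domain(cv, domain_map).domain == "WD1"

    @pytest.mark.parametrize("pos,expected", [(853, "WD1"), (892, "WD1"), (852, None)])
    def test_inclusive_boundaries(self, clf_cfg, domain_map, pos, expected):
        cv = classify_variant(rec(gene="PALB2", protein_pos=pos), clf_cfg)
        # 852 falls between POLH_stimulation (ends 561) and WD1 (starts 853)
        assert assign_domain(cv, domain_map).domain == expected

    def test_outside_all_intervals(self, clf_cfg, domain_map):
        cv = classify_variant(rec(gene="CHEK2", protein_pos=400), clf_cfg)
        assert assign_domain(cv, domain_map).domain == "kinase"
        cv2 = classify_variant(rec(gene="CHEK2", protein_pos=500), clf_cfg)
        assert assign_domain(cv2, domain_map).domain is None

    def test_ptv_and_excluded_pass_through(self, clf_cfg, domain_map):
        ptv = classify_variant(
            rec(gene="PALB2", consequence="stopgain", exon_index=3, protein_pos=860),
            clf_cfg,
        )
        assert assign_domain(ptv, domain_map).domain is None

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainMap(pd.DataFrame({
                "gene": ["G", "G"], "domain": ["a", "b"],
                "residue_start": [1, 50], "residue_end": [60, 100],
            }))

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError, match="start > end"):
            DomainMap(pd.DataFrame({
                "gene": ["G"], "domain": ["a"],
                "residue_start": [60], "residue_end": [10],
            }))

    def test_table_level_assignment(self, clf_cfg, domain_map, rule_fixture):
        classified = assign_domains_table(classify_table(rule_fixture, clf_cfg),
                                          domain_map)
        mis = classified[classified["category"] == "RARE_MISSENSE"]
        # only missense rows get domains; all others stay blank
        assert (classified.loc[classified["category"] != "RARE_MISSENSE",
                               "domain"] == "").all()
        assert len(mis) > 0
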