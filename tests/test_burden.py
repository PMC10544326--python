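"""Carrier-matrix collapse, prevalence tabulation, stratification and the
descriptive two-group comparisons."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelburden.burden import (
    build_carrier_matrix,
    compare_group_location,
    compare_two_proportions,
    stratify,
    subtype_labels,
    tabulate_prevalence,
)
from panelburden.mastos import build_reference_cohort
from panelburden.simulate import CohortConfig, GeneSimSpec, generate_cohort


def tiny_phenotypes(n_cases=4, n_controls=4):
    ids = [f"c{i}" for i in range(n_cases)] + [f"k{i}" for i in range(n_controls)]
    return pd.DataFrame(
        {
            "subject_id": ids,
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "age_years": 50.0,
            "family_history": 0.0,
            "er": "NA", "pr": "NA", "her2": "NA",
        }
    )


def classified_rows(rows):
    base = dict(
        hgvs_c="c.1del", consequence="frameshift_deletion", exon_index=2,
        n_exons=10, af_gnomad_nfe=0.0, clinical_class="pathogenic",
        protein_pos=10, zygosity="het", category="PTV", exclusion_reason="",
        domain="", af_unknown=False,
    )
    return pd.DataFrame([{**base, **r} for r in rows])


class TestCarrierMatrix:
    def test_two_variants_collapse_to_one_indicator(self):
        rows = classified_rows([
            dict(subject_id="c0", gene="BRCA2", variant_id="v1"),
            dict(subject_id="c0", gene="BRCA2", variant_id="v2"),
        ])
        cm = build_carrier_matrix(rows, tiny_phenotypes(), "PTV")
        assert cm.indicator.loc["c0", "BRCA2"] == 1
        assert cm.indicator["BRCA2"].sum() == 1
        assert cm.n_variants["BRCA2"] == 2

    def test_hom_and_het_carriers_identical(self):
        rows = classified_rows([
            dict(subject_id="c0", gene="ATM", variant_id="v1", zygosity="het"),
            dict(subject_id="c1", gene="ATM", variant_id="v1", zygosity="hom"),
        ])
        cm = build_carrier_matrix(rows, tiny_phenotypes(), "PTV")
        assert cm.indicator.loc["c0", "ATM"] == cm.indicator.loc["c1", "ATM"] == 1

    def test_non_carriers_present_as_zero_rows(self):
        rows = classified_rows([dict(subject_id="c0", gene="ATM", variant_id="v1")])
        cm = build_carrier_matrix(rows, tiny_phenotypes(), "PTV")
        assert len(cm.indicator) == 8
        assert cm.indicator.drop("c0").to_numpy().sum() == 0

    def test_orphan_subject_rejected(self):
        rows = classified_rows([dict(subject_id="ghost", gene="ATM", variant_id="v1")])
        with pytest.raises(ValueError, match="ghost"):
            build_carrier_matrix(rows, tiny_phenotypes(), "PTV")

    def test_reference_counts_by_status(self):
        """The reconstructed published cohort reproduces the printed
        per-gene carrier sums (e.g. 18 case vs 1 control for BRCA2)."""
        phen, cm, _ = build_reference_cohort()
        case_ids = phen.loc[phen["status"] == "case", "subject_id"]
        ctrl_ids = phen.loc[phen["status"] == "control", "subject_id"]
        assert cm.indicator.loc[case_ids, "BRCA2"].sum() == 18
        assert cm.indicator.loc[ctrl_ids, "BRCA2"].sum() == 1
        assert cm.indicator.loc[case_ids, "ATM"].sum() == 9
        assert cm.indicator.loc[ctrl_ids, "CHEK2"].sum() == 1


class TestPrevalence:
    def test_percentages_recompute_from_counts(self):
        phen, cm, _ = build_reference_cohort()
        table = tabulate_prevalence(cm, phen)
        for _, row in table.iterrows():
            assert row["case_prevalence_pct"] == pytest.approx(
                100.0 * row["n_case_carriers"] / 990
            )
            assert row["control_prevalence_pct"] == pytest.approx(
                100.0 * row["n_control_carriers"] / 1094
            )

    def test_gene_set_counts_subjects_once(self):
        phen = tiny_phenotypes()
        rows = classified_rows([
            dict(subject_id="c0", gene="BRCA1", variant_id="v1"),
            dict(subject_id="c0", gene="BRCA2", variant_id="v2"),
            dict(subject_id="c1", gene="BRCA2", variant_id="v3"),
        ])
        cm = build_carrier_matrix(rows, phen, "PTV")
        table = tabulate_prevalence(cm, phen, {"pair": ["BRCA1", "BRCA2"]})
        pair = table[table["unit"] == "pair"].iloc[0]
        assert pair["n_case_carriers"] == 2  # c0 counted once
        # aggregate <= sum of member counts, equality iff no overlap
        members = table[table["unit"].isin(["BRCA1", "BRCA2"])]
        assert pair["n_case_carriers"] <= members["n_case_carriers"].sum()
        assert pair["n_case_carriers"] < members["n_case_carriers"].sum()

    def test_zero_carrier_unit_is_zero_percent(self):
        phen = tiny_phenotypes()
        rows = classified_rows([
            dict(subject_id="c0", gene="ATM", variant_id="v1"),
            dict(subject_id="k0", gene="RAD50", variant_id="v2",
                 category="EXCLUDED", exclusion_reason="last_exon"),
        ])
        cm = build_carrier_matrix(rows, phen, "PTV")
        assert "RAD50" not in cm.units  # excluded rows never reach the matrix

    def test_empty_group_rejected(self):
        phen = tiny_phenotypes(n_controls=4).assign(status="case")
        rows = classified_rows([dict(subject_id="c0", gene="ATM", variant_id="v1")])
        cm = build_carrier_matrix(rows, phen, "PTV")
        with pytest.raises(ValueError, match="non-empty"):
            tabulate_prevalence(cm, phen)

    def test_domain_level_units(self):
        phen = tiny_phenotypes()
        rows = classified_rows([
            dict(subject_id="c0", gene="PALB2", variant_id="v1",
                 category="RARE_MISSENSE", domain="WD1",
                 consequence="nonsynonymous_SNV"),
            dict(subject_id="c1", gene="PALB2", variant_id="v2",
                 category="RARE_MISSENSE", domain="",
                 consequence="nonsynonymous_SNV"),
        ])
        cm = build_carrier_matrix(rows, phen, "RARE_MISSENSE", "domain")
        assert cm.units == ["PALB2:WD1"]
        assert cm.indicator["PALB2:WD1"].sum() == 1


class TestStratification:
    def test_family_history_partition_sizes(self):
        """Published margins: 158 FH-yes / 815 FH-no / 17 missing cases."""
        phen, _, _ = build_reference_cohort()
        cases = phen[phen["status"] == "case"]
        parts, dropped = stratify(cases, "family_history")
        assert len(parts["fh_yes"]) == 158
        assert len(parts["fh_no"]) == 815
        assert len(dropped) == 17

    def test_age_cut_partition_is_complete(self):
        phen, _ = generate_cohort(CohortConfig(
            seed=5, per_gene=(GeneSimSpec("G", 0.01),)))
        parts, dropped = stratify(phen, "age_cut")
        assert len(parts["age_lt50"]) + len(parts["age_ge50"]) + len(dropped) == len(phen)
        assert len(dropped) == 0

    def test_triple_negative_share_of_fully_typed(self):
        phen, _, _ = build_reference_cohort()
        labels = subtype_labels(phen)
        typed = labels["triple_negative"].notna().sum()
        tn = (labels["triple_negative"] == True).sum()  # noqa: E712
        assert typed == 576
        assert tn == 66
        assert round(100.0 * tn / typed, 1) == 11.5

    def test_subtype_marker_counts_sum_to_observed(self):
        phen, _ = generate_cohort(CohortConfig(
            seed=6, per_gene=(GeneSimSpec("G", 0.01),)))
        labels = subtype_labels(phen)
        cases = phen["status"] == "case"
        for marker in ("er", "pr", "her2"):
            observed = (phen.loc[cases.to_numpy(), marker] != "NA").sum()
            pos = (labels[f"{marker}_pos"] == True).sum()  # noqa: E712
            neg = (labels[f"{marker}_neg"] == True).sum()  # noqa: E712
            assert pos + neg == observed

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError, match="stratifier"):
            stratify(tiny_phenotypes(), "tumor_grade")


class TestLocationComparison:
    def test_identical_groups_rank_sum_p_is_one(self):
        res = compare_group_location([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["p"] == pytest.approx(1.0)

    def test_tiny_groups_match_exact_enumeration(self):
        """n=2 vs n=2: exact rank-sum null from all 4!/(2!2!) splits."""
        x, y = [1.0, 2.0], [3.0, 4.0]
        res = compare_group_location(x, y)
        pooled = sorted(x + y)
        stats_all = []
        for combo in itertools.combinations(range(4), 2):
            u = sum(
                1
                for i in combo
                for j in set(range(4)) - set(combo)
                if pooled[i] > pooled[j]
            )
            stats_all.append(u)
        observed = 0  # all of x below all of y
        p_exact = np.mean([
            min(s, 4 - s) <= min(observed, 4 - observed) for s in stats_all
        ])
        assert res["statistic"] == observed
        assert res["p"] == pytest.approx(p_exact)

    def test_shift_detected_against_permutation_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 9, 120)
        y = x[:60] + 10.0
        res = compare_group_location(x, y)
        assert res["p"] < 1e-3
        # permutation oracle on the difference of means
        pooled = np.r_[x, y]
        obs = abs(x.mean() - y.mean())
        count = 0
        for _ in range(2000):
            perm = rng.permutation(pooled)
            count += abs(perm[:120].mean() - perm[120:].mean()) >= obs
        assert count / 2000 < 1e-3

    def test_t_test_reports_summaries(self):
        res = compare_group_location([1, 2, 3], [4, 5, 6], method="t_test")
        assert res["mean_x"] == 2.0 and res["mean_y"] == 5.0
        expected = stats.ttest_ind([1, 2, 3], [4, 5, 6]).pvalue
        assert res["p"] == pytest.approx(float(expected))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_group_location([], [1.0])
        with pytest.raises(ValueError, match="at least 2"):
            compare_group_location([1.0], [2.0, 3.0], method="t_test")


class TestProportionComparison:
    def test_identical_proportions_p_one(self):
        assert compare_two_proportions(5, 10, 5, 10) == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric_enumeration(self):
        """(0/10 vs 10/10): two-sided Fisher p from direct enumeration of
        the hypergeometric null."""
        p = compare_two_proportions(0, 10, 10, 10)
        # P(X = k) for k successes in the first margin, X ~ Hypergeom(20, 10, 10)
        pmf = [stats.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_obs = pmf[0]
        p_exact = sum(q for q in pmf if q <= p_obs + 1e-12)
        assert p == pytest.approx(p_exact, rel=1e-8)
        assert p < 1e-3

    def test_published_family_history_contrast_is_significant(self):
        """13/158 vs 29/815 carriers: significant at 0.05 under both
        supported methods (the chi-square p reproduces 0.015)."""
        assert compare_two_proportions(13, 158, 29, 815) <= 0.05
        assert compare_two_proportions(13, 158, 29, 815, "chi2") == pytest.approx(
            0.015, abs=5e-4
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="invalid counts"):
            compare_two_proportions(11, 10, 1, 10)
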