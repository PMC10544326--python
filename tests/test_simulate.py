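"""Synthetic-cohort generator: determinism, marginal fidelity, null
symmetry, agreement with a forward source-population simulation, and the
incidence presets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from panelburden.classify import ClassificationConfig, classify_table
from panelburden.simulate import (
    AgeBands,
    CohortConfig,
    ConfigError,
    GeneSimSpec,
    generate_cohort,
    generate_incidence_table,
    simulate_case_control,
)


def small_cfg(seed=11, **kw):
    defaults = dict(
        seed=seed,
        per_gene=(
            GeneSimSpec("BRCA2", 9e-4, np.log(9.75), n_exons=27,
                        founder_fraction=0.55, founder_hgvs="c.8756delG"),
            GeneSimSpec("CHEK2", 0.01, 0.0, n_exons=15,
                        missense_freq_controls=0.02),
        ),
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestShapesAndDeterminism:
    def test_row_counts(self):
        phen, _ = generate_cohort(small_cfg())
        assert len(phen) == 990 + 1094
        assert (phen["status"] == "case").sum() == 990
        assert (phen["status"] == "control").sum() == 1094

    def test_same_seed_identical_different_seed_differs(self):
        p1, v1 = generate_cohort(small_cfg(seed=3))
        p2, v2 = generate_cohort(small_cfg(seed=3))
        p3, v3 = generate_cohort(small_cfg(seed=4))
        assert p1.equals(p2) and v1.equals(v2)
        assert not v1.equals(v3)

    def test_controls_have_no_receptor_data(self):
        phen, _ = generate_cohort(small_cfg())
        ctrl = phen[phen["status"] == "control"]
        assert (ctrl[["er", "pr", "her2"]] == "NA").all().all()

    def test_variant_table_exercises_every_rule(self):
        _, variants = generate_cohort(small_cfg())
        classified = classify_table(variants, ClassificationConfig())
        reasons = set(classified.loc[classified["category"] == "EXCLUDED",
                                     "exclusion_reason"])
        assert reasons == {
            "gene_excluded", "consequence_out_of_scope", "last_exon",
            "penultimate_splice", "uncertain_splice", "benign", "common",
        }
        assert (classified["category"] == "PTV").any()
        assert (classified["category"] == "RARE_MISSENSE").any()

    def test_founder_variant_dominates_brca2(self):
        _, variants = generate_cohort(small_cfg(seed=20))
        brca2 = variants[(variants["gene"] == "BRCA2")
                         & (variants["consequence"] != "nonsynonymous_SNV")]
        qualifying = brca2[~brca2["variant_id"].str.contains("decoy")]
        assert (qualifying["hgvs_c"] == "c.8756delG").any()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(n_cases=0), "n_cases"),
            (dict(n_controls=-5), "n_controls"),
            (dict(fh_prob_cases=1.5), "fh_prob_cases"),
            (dict(noise_rate=-1), "noise_rate"),
        ],
    )
    def test_bad_scalar_config_names_field(self, kw, field):
        with pytest.raises(ConfigError, match=field):
            small_cfg(**kw)

    def test_duplicate_gene_names_rejected(self):
        genes = (GeneSimSpec("G", 0.01), GeneSimSpec("G", 0.02))
        with pytest.raises(ConfigError, match="unique"):
            CohortConfig(seed=1, per_gene=genes)

    def test_bad_gene_spec(self):
        with pytest.raises(ConfigError, match="carrier_freq"):
            GeneSimSpec("G", 1.2)
        with pytest.raises(ConfigError, match="founder_fraction"):
            GeneSimSpec("G", 0.01, founder_fraction=1.3)

    def test_bad_age_bands(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            AgeBands(((20.0, 30.0, 0.4), (30.0, 40.0, 0.4)))


class TestStatisticalStructure:
    def test_marginal_fidelity_large_n(self):
        """Family-history and carrier frequencies converge to the
        configured values (checked at n = 50,000 within 3 binomial SEs)."""
        n = 25_000
        cfg = CohortConfig(
            seed=99, n_cases=n, n_controls=n,
            per_gene=(GeneSimSpec("G", 0.01, np.log(2.0)),),
        )
        df = simulate_case_control(cfg)
        ctrl = df[df["status"] == "control"]
        f_hat = ctrl["carrier_G"].mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(f_hat - 0.01) < 3 * se
        fh_obs = df.loc[df["status"] == "case", "family_history"].dropna().mean()
        se_fh = np.sqrt(cfg.fh_prob_cases * (1 - cfg.fh_prob_cases) / n)
        assert abs(fh_obs - cfg.fh_prob_cases) < 3.5 * se_fh

    def test_null_effect_symmetry(self):
        """With log OR = 0 case and control carrier frequencies agree
        within Monte-Carlo error."""
        n = 25_000
        cfg = CohortConfig(
            seed=7, n_cases=n, n_controls=n,
            per_gene=(GeneSimSpec("G", 0.01, 0.0),),
        )
        df = simulate_case_control(cfg)
        p_case = df.loc[df["status"] == "case", "carrier_G"].mean()
        p_ctrl = df.loc[df["status"] == "control", "carrier_G"].mean()
        se = np.sqrt(2 * 0.01 * 0.99 / n)
        assert abs(p_case - p_ctrl) < 3 * se

    def test_effect_realism_against_forward_simulation(self):
        """The conditional carrier draw agrees with a brute-force forward
        simulation of the retrospective design (source population with a
        logistic disease model, fixed numbers of cases/controls sampled)."""
        f, log_or = 1e-3, np.log(9.75)
        n_cases, n_controls, reps = 990, 1094, 40

        def forward(seed):
            rng = np.random.default_rng(seed)
            N = 600_000
            carrier = rng.random(N) < f
            p = expit(logit(0.005) + log_or * carrier)
            case = rng.random(N) < p
            case_idx = np.flatnonzero(case)
            ctrl_idx = np.flatnonzero(~case)
            ci = rng.choice(case_idx, n_cases, replace=False)
            ki = rng.choice(ctrl_idx, n_controls, replace=False)
            return carrier[ci].sum(), carrier[ki].sum()

        fwd = np.array([forward(1000 + i) for i in range(reps)], dtype=float)
        gen = []
        for i in range(reps):
            cfg = CohortConfig(seed=2000 + i, per_gene=(GeneSimSpec("G", f, log_or),))
            df = simulate_case_control(cfg)
            gen.append(
                (
                    df.loc[df["status"] == "case", "carrier_G"].sum(),
                    df.loc[df["status"] == "control", "carrier_G"].sum(),
                )
            )
        gen = np.array(gen, dtype=float)
        for col in (0, 1):
            diff = fwd[:, col].mean() - gen[:, col].mean()
            se = np.sqrt(fwd[:, col].var(ddof=1) / reps + gen[:, col].var(ddof=1) / reps)
            assert abs(diff) < 3 * max(se, 0.1), (col, diff, se)

    def test_subtype_effect_enriches_er_negative_cases(self):
        n = 20_000
        cfg = CohortConfig(
            seed=31, n_cases=n, n_controls=n,
            per_gene=(GeneSimSpec("G", 0.005, 0.0, subtype_log_or=np.log(8.0)),),
        )
        df = simulate_case_control(cfg)
        cases = df[df["status"] == "case"]
        p_neg = cases.loc[cases["er_latent"] == "neg", "carrier_G"].mean()
        p_pos = cases.loc[cases["er_latent"] == "pos", "carrier_G"].mean()
        assert p_neg > 3 * p_pos


class TestIncidenceGenerator:
    def test_constant_preset(self):
        inc = generate_incidence_table("constant", 0.001, 80)
        assert len(inc) == 16
        assert (inc["rate_per_py"] == 0.001).all()
        assert inc["age_start"].iloc[0] == 0 and inc["age_end"].iloc[-1] == 80

    def test_bc_like_population_risk_between_5_and_15_pct(self):
        inc = generate_incidence_table("bc-like", 1.0, 80)
        # closed form: 1 - exp(-sum lambda * dt)
        risk = 1.0 - np.exp(-np.sum(inc["rate_per_py"] * 5.0))
        assert 0.05 < risk < 0.15

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigError, match="scale"):
            generate_incidence_table("constant", 0.0, 80)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigError, match="shape"):
            generate_incidence_table("bathtub", 1.0, 80)
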