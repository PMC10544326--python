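"""Synthetic case-control cohort generator.

Emulates a population-based breast-cancer case-control study of the
MASTOS type — 990 cases and 1,094 age-matched controls with the
published age-band, family-history and tumor-receptor structure — plus
an annotated variant table, a protein-domain map and a population
incidence table, so the whole downstream pipeline is testable without
any external data.

Disease model.  The design is retrospective: case/control status follows
a logistic model P(case | carriers, age, FH) with configured per-gene
log-odds-ratios, and fixed numbers of cases and controls are sampled.
The generator draws the equivalent conditional form directly: covariates
are drawn per group from the configured marginals, and carrier status is
drawn conditional on status by Bayes inversion of the logistic model —
carrier odds in cases equal the control carrier odds times the
(age- and subtype-specific) odds ratio.  Under covariate-independent
exposure in the source population the two schemes are the same model,
and the logistic OR is the exact estimand.

Every table gets its own RNG stream derived from the master seed, so the
output is bit-reproducible and adding one table never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .classify import DEFAULT_PANEL_GENES, DomainMap, EXCLUDED_BRCA1_SPLICE

__all__ = [
    "ConfigError",
    "AgeBands",
    "ReceptorModel",
    "GeneSimSpec",
    "CohortConfig",
    "generate_cohort",
    "simulate_case_control",
    "generate_incidence_table",
    "default_domain_map",
    "write_tables",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


# --- published marginal structure used as generator defaults -------------
# cases: age bands <=29 / 30-39 / 40-49 / 50-59 / >=60 with the reported
# band frequencies; observed case ages span 26-74 and control ages 28-71.
DEFAULT_AGE_BANDS_CASES: tuple = (
    (26.0, 30.0, 5 / 990),
    (30.0, 40.0, 87 / 990),
    (40.0, 50.0, 349 / 990),
    (50.0, 60.0, 344 / 990),
    (60.0, 75.0, 205 / 990),
)
DEFAULT_AGE_BANDS_CONTROLS: tuple = (
    (28.0, 30.0, 2 / 1091),
    (30.0, 40.0, 8 / 1091),
    (40.0, 50.0, 178 / 1091),
    (50.0, 60.0, 566 / 1091),
    (60.0, 72.0, 337 / 1091),
)
DEFAULT_FH_PROB_CASES = 158 / 973
DEFAULT_FH_PROB_CONTROLS = 87 / 1091
DEFAULT_FH_MISSING_CASES = 17 / 990
DEFAULT_FH_MISSING_CONTROLS = 3 / 1094


@dataclass(frozen=True)
class AgeBands:
    """Piecewise-uniform age distribution: (low, high, probability) bands
    with uniform jitter within each band."""

    bands: tuple

    def __post_init__(self):
        probs = np.array([b[2] for b in self.bands], dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
            raise ConfigError("age_distribution: band probabilities must be >= 0 and sum to 1")
        for low, high, _ in self.bands:
            if not low < high:
                raise ConfigError(f"age_distribution: band [{low}, {high}) is empty")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        probs = np.array([b[2] for b in self.bands], dtype=float)
        probs = probs / probs.sum()
        idx = rng.choice(len(self.bands), size=n, p=probs)
        lows = np.array([b[0] for b in self.bands])[idx]
        highs = np.array([b[1] for b in self.bands])[idx]
        return np.round(lows + rng.random(n) * (highs - lows), 1)


@dataclass(frozen=True)
class ReceptorModel:
    """Tumor-marker model for cases: marginal positivity probabilities and
    independent per-marker missingness (controls are always missing)."""

    er_pos: float = 476 / 628
    pr_pos: float = 381 / 619
    her2_pos: float = 94 / 584
    miss_er: float = 362 / 990
    miss_pr: float = 371 / 990
    miss_her2: float = 406 / 990

    def __post_init__(self):
        for name in ("er_pos", "pr_pos", "her2_pos", "miss_er", "miss_pr", "miss_her2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"receptor model: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneSimSpec:
    """Simulation parameters for one gene.

    ``carrier_freq_controls`` is the PTV carrier frequency among
    controls; ``log_or`` the disease log-odds-ratio for PTV carriers;
    ``subtype_log_or`` an optional additional effect restricted to
    ER-negative disease; ``log_or_per_year`` an effect-modification
    slope (log OR change per year of age, centered at 50);
    ``founder_fraction`` the fraction of carriers sharing one designated
    founder variant.  Optional missense fields drive the rare-missense
    scan; they default to zero (no missense variation simulated).
    """

    gene: str
    carrier_freq_controls: float
    log_or: float = 0.0
    subtype_log_or: float | None = None
    log_or_per_year: float = 0.0
    n_exons: int = 20
    founder_fraction: float = 0.0
    founder_hgvs: str | None = None
    missense_freq_controls: float = 0.0
    missense_log_or: float = 0.0
    protein_length: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.carrier_freq_controls < 1.0):
            raise ConfigError(
                f"gene {self.gene}: carrier_freq_controls={self.carrier_freq_controls} "
                "outside [0, 1)"
            )
        if not (0.0 <= self.founder_fraction <= 1.0):
            raise ConfigError(f"gene {self.gene}: founder_fraction outside [0, 1]")
        if not (0.0 <= self.missense_freq_controls < 1.0):
            raise ConfigError(f"gene {self.gene}: missense_freq_controls outside [0, 1)")
        if self.n_exons < 3:
            raise ConfigError(f"gene {self.gene}: n_exons must be >= 3")

    @property
    def plen(self) -> int:
        return self.protein_length or self.n_exons * 60


DEFAULT_GENES = (
    GeneSimSpec("BRCA2", 9e-4, np.log(9.75), n_exons=27, founder_fraction=0.55,
                founder_hgvs="c.8756delG", protein_length=3418,
                missense_freq_controls=0.01),
    GeneSimSpec("ATM", 9e-4, np.log(7.61), n_exons=63, protein_length=3056,
                missense_freq_controls=0.03),
    GeneSimSpec("BRCA1", 9e-4, np.log(3.18), subtype_log_or=np.log(20.73 / 3.18),
                n_exons=23, protein_length=1863, missense_freq_controls=0.01),
    GeneSimSpec("PALB2", 5e-4, np.log(16.14), n_exons=13, protein_length=1186,
                missense_freq_controls=0.01),
    GeneSimSpec("CHEK2", 9e-4, 0.0, n_exons=15, protein_length=543,
                missense_freq_controls=0.02),
    GeneSimSpec("RAD50", 9e-4, np.log(3.83), n_exons=25, protein_length=1312),
    GeneSimSpec("FANCC", 1.8e-3, 0.0, n_exons=15, protein_length=558),
    GeneSimSpec("RECQL", 2.7e-3, 0.0, n_exons=15, protein_length=649),
)


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration; ``seed`` is required."""

    seed: int
    n_cases: int = 990
    n_controls: int = 1094
    age_cases: AgeBands = field(default_factory=lambda: AgeBands(DEFAULT_AGE_BANDS_CASES))
    age_controls: AgeBands = field(default_factory=lambda: AgeBands(DEFAULT_AGE_BANDS_CONTROLS))
    fh_prob_cases: float = DEFAULT_FH_PROB_CASES
    fh_prob_controls: float = DEFAULT_FH_PROB_CONTROLS
    fh_missing_cases: float = DEFAULT_FH_MISSING_CASES
    fh_missing_controls: float = DEFAULT_FH_MISSING_CONTROLS
    receptors: ReceptorModel = field(default_factory=ReceptorModel)
    per_gene: tuple = DEFAULT_GENES
    noise_rate: float = 0.05  # expected rule-exercising decoy rows per subject
    age_ref: float = 50.0  # centering for the per-year OR slope

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ConfigError(f"n_cases={self.n_cases} must be positive")
        if self.n_controls <= 0:
            raise ConfigError(f"n_controls={self.n_controls} must be positive")
        for name in ("fh_prob_cases", "fh_prob_controls", "fh_missing_cases", "fh_missing_controls"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        names = [g.gene for g in self.per_gene]
        if len(names) != len(set(names)):
            raise ConfigError("per_gene: gene names must be unique")
        if self.noise_rate < 0:
            raise ConfigError(f"noise_rate={self.noise_rate} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("seed is required")
        if "per_gene" in d:
            d["per_gene"] = tuple(
                g if isinstance(g, GeneSimSpec) else GeneSimSpec(**g) for g in d["per_gene"]
            )
        if "age_cases" in d and not isinstance(d["age_cases"], AgeBands):
            d["age_cases"] = AgeBands(tuple(tuple(b) for b in d["age_cases"]))
        if "age_controls" in d and not isinstance(d["age_controls"], AgeBands):
            d["age_controls"] = AgeBands(tuple(tuple(b) for b in d["age_controls"]))
        if "receptors" in d and not isinstance(d["receptors"], ReceptorModel):
            d["receptors"] = ReceptorModel(**d["receptors"])
        return cls(**d)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_case_control(cfg: CohortConfig) -> pd.DataFrame:
    """Subject-level frame: phenotypes, latent receptor states and one
    ``carrier_<gene>`` / ``missense_<gene>`` 0/1 column per gene.

    This is the statistical core used both by :func:`generate_cohort`
    (which realizes variant rows on top of it) and directly by
    simulation studies that only need carrier indicators.
    """
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(2 + 2 * len(cfg.per_gene))
    rng_phen = np.random.default_rng(streams[0])

    n = cfg.n_cases + cfg.n_controls
    status = np.array(["case"] * cfg.n_cases + ["control"] * cfg.n_controls)
    is_case = status == "case"
    subject_id = np.array(
        [f"case_{i + 1:05d}" for i in range(cfg.n_cases)]
        + [f"ctrl_{i + 1:05d}" for i in range(cfg.n_controls)]
    )
    age = np.empty(n)
    age[is_case] = cfg.age_cases.sample(cfg.n_cases, rng_phen)
    age[~is_case] = cfg.age_controls.sample(cfg.n_controls, rng_phen)

    fh = np.where(
        is_case,
        (rng_phen.random(n) < cfg.fh_prob_cases).astype(float),
        (rng_phen.random(n) < cfg.fh_prob_controls).astype(float),
    )
    fh_missing = np.where(
        is_case,
        rng_phen.random(n) < cfg.fh_missing_cases,
        rng_phen.random(n) < cfg.fh_missing_controls,
    )
    fh[fh_missing] = np.nan

    rm = cfg.receptors
    er_lat = np.where(rng_phen.random(n) < rm.er_pos, "pos", "neg")
    pr_lat = np.where(rng_phen.random(n) < rm.pr_pos, "pos", "neg")
    her2_lat = np.where(rng_phen.random(n) < rm.her2_pos, "pos", "neg")
    er = np.where(is_case & (rng_phen.random(n) >= rm.miss_er), er_lat, "NA")
    pr = np.where(is_case & (rng_phen.random(n) >= rm.miss_pr), pr_lat, "NA")
    her2 = np.where(is_case & (rng_phen.random(n) >= rm.miss_her2), her2_lat, "NA")

    out = pd.DataFrame(
        {
            "subject_id": subject_id,
            "status": status,
            "age_years": age,
            "family_history": fh,
            "er": er,
            "pr": pr,
            "her2": her2,
            "er_latent": er_lat,
        }
    )

    for k, g in enumerate(cfg.per_gene):
        rng_g = np.random.default_rng(streams[2 + 2 * k])
        # PTV carriers: controls at f; cases at the OR-shifted odds
        if g.carrier_freq_controls > 0:
            lo = _logit(g.carrier_freq_controls)
            lor = np.full(n, g.log_or)
            if g.subtype_log_or is not None:
                lor = lor + np.where(er_lat == "neg", g.subtype_log_or, 0.0)
            lor = lor + g.log_or_per_year * (age - cfg.age_ref)
            p = np.where(is_case, _expit(lo + lor), g.carrier_freq_controls)
            out[f"carrier_{g.gene}"] = (rng_g.random(n) < p).astype(np.int8)
        else:
            out[f"carrier_{g.gene}"] = np.zeros(n, dtype=np.int8)
        if g.missense_freq_controls > 0:
            lo = _logit(g.missense_freq_controls)
            p = np.where(
                is_case, _expit(lo + g.missense_log_or), g.missense_freq_controls
            )
            out[f"missense_{g.gene}"] = (rng_g.random(n) < p).astype(np.int8)
        else:
            out[f"missense_{g.gene}"] = np.zeros(n, dtype=np.int8)
    return out


# --------------------------------------------------------------------------
# variant realization
# --------------------------------------------------------------------------


def _ptv_pool(g: GeneSimSpec, rng: np.random.Generator, size: int = 12) -> list[dict]:
    """Deterministic per-gene pool of qualifying PTV definitions (never in
    the last exon; splice variants never in the penultimate exon)."""
    pool = []
    for k in range(size):
        cons = rng.choice(
            ["stopgain", "frameshift_deletion", "frameshift_insertion", "splicing"]
        )
        if cons == "splicing":
            exon = int(rng.integers(1, max(2, g.n_exons - 1)))  # 1 .. n_exons-2
            cpos = int(rng.integers(100, g.plen * 3))
            hgvs = f"c.{cpos}+{rng.integers(1, 3)}G>A"
        else:
            exon = int(rng.integers(1, g.n_exons))  # 1 .. n_exons-1
            cpos = int(rng.integers(100, g.plen * 3))
            hgvs = {
                "stopgain": f"c.{cpos}C>T",
                "frameshift_deletion": f"c.{cpos}del",
                "frameshift_insertion": f"c.{cpos}dup",
            }[cons]
        pool.append(
            {
                "variant_id": f"{g.gene}_ptv{k:02d}",
                "hgvs_c": hgvs,
                "consequence": cons,
                "exon_index": exon,
                "n_exons": g.n_exons,
                "af_gnomad_nfe": float(np.round(rng.random() * 5e-5, 7)),
                "clinical_class": str(rng.choice(["pathogenic", "unclassified"], p=[0.8, 0.2])),
                "protein_pos": max(1, cpos // 3),
            }
        )
    return pool


def _missense_pool(g: GeneSimSpec, rng: np.random.Generator, size: int = 20) -> list[dict]:
    pool = []
    for k in range(size):
        pos = int(rng.integers(1, g.plen + 1))
        af = float(np.round(rng.random() * 9e-4, 7))
        if rng.random() < 0.1:
            af = np.nan  # absent from gnomAD; kept as rare but flagged
        pool.append(
            {
                "variant_id": f"{g.gene}_mis{k:02d}",
                "hgvs_c": f"c.{3 * pos - 1}G>A",
                "consequence": "nonsynonymous_SNV",
                "exon_index": int(rng.integers(1, g.n_exons + 1)),
                "n_exons": g.n_exons,
                "af_gnomad_nfe": af,
                "clinical_class": str(rng.choice(["vus", "unclassified"], p=[0.7, 0.3])),
                "protein_pos": pos,
            }
        )
    return pool


_DECOY_TEMPLATES = (
    "last_exon_ptv",
    "penultimate_splice",
    "brca1_uncertain_splice",
    "common_missense",
    "benign_missense",
    "inframe_indel",
    "utr",
    "intronic",
    "synonymous",
    "ppm1d",
)


def _decoy_row(template: str, gene_exons: dict, rng: np.random.Generator) -> dict:
    genes = sorted(gene_exons)
    gene = str(rng.choice(genes))
    nex = gene_exons[gene]
    cpos = int(rng.integers(100, 5000))
    base = {
        "gene": gene,
        "variant_id": f"{gene}_decoy_{template}_{rng.integers(1e6):06d}",
        "hgvs_c": f"c.{cpos}G>A",
        "consequence": "nonsynonymous_SNV",
        "exon_index": int(rng.integers(1, nex + 1)),
        "n_exons": nex,
        "af_gnomad_nfe": float(np.round(rng.random() * 9e-4, 7)),
        "clinical_class": "unclassified",
        "protein_pos": max(1, cpos // 3),
    }
    if template == "last_exon_ptv":
        base.update(
            consequence=str(rng.choice(["stopgain", "frameshift_deletion"])),
            exon_index=nex, hgvs_c=f"c.{cpos}C>T",
        )
    elif template == "penultimate_splice":
        # non-exception gene so the rule fires
        gene = str(rng.choice([g for g in genes if g not in
                               {"ATM", "BARD1", "BRCA1", "RAD51C", "RAD51D", "PALB2"}] or ["CHEK2"]))
        nex = gene_exons.get(gene, 15)
        base.update(gene=gene, n_exons=nex, consequence="splicing",
                    exon_index=nex - 1, hgvs_c=f"c.{cpos}+2T>C",
                    variant_id=f"{gene}_decoy_{template}_{rng.integers(1e6):06d}")
    elif template == "brca1_uncertain_splice":
        hgvs = str(rng.choice(sorted(h for _, h in EXCLUDED_BRCA1_SPLICE)))
        nex = gene_exons.get("BRCA1", 23)
        base.update(gene="BRCA1", n_exons=nex, consequence="splicing",
                    exon_index=int(rng.integers(1, nex - 1)), hgvs_c=hgvs,
                    variant_id=f"BRCA1_decoy_{template}_{rng.integers(1e6):06d}")
    elif template == "common_missense":
        base.update(af_gnomad_nfe=float(np.round(0.001 + rng.random() * 0.05, 6)))
    elif template == "benign_missense":
        base.update(clinical_class=str(rng.choice(["benign", "likely_benign"])))
    elif template == "inframe_indel":
        base.update(consequence=str(rng.choice(["nonframeshift_insertion",
                                                "nonframeshift_deletion"])),
                    hgvs_c=f"c.{cpos}_{cpos + 2}del")
    elif template == "utr":
        base.update(consequence=str(rng.choice(["UTR5", "UTR3"])), protein_pos=np.nan)
    elif template == "intronic":
        base.update(consequence="intronic", protein_pos=np.nan)
    elif template == "synonymous":
        base.update(consequence="synonymous_SNV")
    elif template == "ppm1d":
        base.update(gene="PPM1D", n_exons=6, exon_index=3, consequence="stopgain",
                    hgvs_c=f"c.{cpos}C>T",
                    variant_id=f"PPM1D_decoy_{rng.integers(1e6):06d}")
    return base


VARIANT_COLUMNS = [
    "subject_id", "gene", "variant_id", "hgvs_c", "consequence", "exon_index",
    "n_exons", "af_gnomad_nfe", "clinical_class", "protein_pos", "zygosity",
]
PHENOTYPE_COLUMNS = ["subject_id", "status", "age_years", "family_history", "er", "pr", "her2"]


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (phenotype table, variant table).

    The phenotype table has exactly n_cases + n_controls rows.  The
    variant table holds one row per (subject, variant): qualifying PTVs
    and rare missense variants realized for the simulated carriers, plus
    rule-exercising decoy rows (last-exon PTVs, penultimate-exon splice
    variants, named uncertain BRCA1 splice variants, common and benign
    missense, in-frame indels, UTR/intronic/synonymous rows, and PPM1D
    rows) that the classifier must exclude.  Identical config and seed
    give byte-identical tables.
    """
    subjects = simulate_case_control(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(2 + 2 * len(cfg.per_gene))
    rng_decoy = np.random.default_rng(streams[1])

    gene_exons = {g.gene: g.n_exons for g in cfg.per_gene}
    for gname in sorted(DEFAULT_PANEL_GENES):
        gene_exons.setdefault(gname, 15)

    rows: list[dict] = []
    for k, g in enumerate(cfg.per_gene):
        rng_v = np.random.default_rng(streams[2 + 2 * k + 1])
        pool = _ptv_pool(g, rng_v)
        founder = None
        if g.founder_fraction > 0:
            founder = {
                "variant_id": f"{g.gene}_founder",
                "hgvs_c": g.founder_hgvs or f"c.{int(rng_v.integers(100, g.plen * 3))}del",
                "consequence": "frameshift_deletion",
                "exon_index": max(1, g.n_exons // 2),
                "n_exons": g.n_exons,
                "af_gnomad_nfe": 0.0,
                "clinical_class": "pathogenic",
                "protein_pos": g.plen // 2,
            }
        carriers = subjects.loc[subjects[f"carrier_{g.gene}"] == 1, "subject_id"]
        for sid in carriers:
            if founder is not None and rng_v.random() < g.founder_fraction:
                var = founder
            else:
                var = pool[int(rng_v.integers(len(pool)))]
            zyg = "hom" if rng_v.random() < 0.01 else "het"
            rows.append({"subject_id": sid, "gene": g.gene, **var, "zygosity": zyg})
            if rng_v.random() < 0.02:  # occasional second distinct PTV
                var2 = pool[int(rng_v.integers(len(pool)))]
                if var2["variant_id"] != var["variant_id"]:
                    rows.append({"subject_id": sid, "gene": g.gene, **var2, "zygosity": "het"})
        mpool = _missense_pool(g, rng_v)
        mcarriers = subjects.loc[subjects[f"missense_{g.gene}"] == 1, "subject_id"]
        for sid in mcarriers:
            var = mpool[int(rng_v.integers(len(mpool)))]
            rows.append({"subject_id": sid, "gene": g.gene, **var, "zygosity": "het"})

    # decoys: at least one per template, plus Poisson extras
    sids = subjects["subject_id"].to_numpy()
    n_extra = int(rng_decoy.poisson(cfg.noise_rate * len(sids)))
    templates = list(_DECOY_TEMPLATES) + [
        str(rng_decoy.choice(_DECOY_TEMPLATES)) for _ in range(n_extra)
    ]
    for template in templates:
        sid = str(rng_decoy.choice(sids))
        rows.append({"subject_id": sid, **_decoy_row(template, gene_exons, rng_decoy),
                     "zygosity": "het"})

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    variants = variants.sort_values(["subject_id", "gene", "variant_id"]).reset_index(drop=True)
    phenotypes = subjects[PHENOTYPE_COLUMNS].copy()
    return phenotypes, variants


# --------------------------------------------------------------------------
# incidence table and domain map
# --------------------------------------------------------------------------

# synthetic breast-cancer-like incidence preset: near-zero before 25,
# rising to a plateau of 2.5 per 1,000 person-years in the 60s; the
# implied population cumulative risk to 80 is ~9.4%
_BC_LIKE_RATES = (
    0.0, 0.0, 0.0, 0.0, 5e-5, 2e-4, 5e-4, 1e-3,
    1.5e-3, 2e-3, 2.2e-3, 2.4e-3, 2.5e-3, 2.5e-3, 2.5e-3, 2.5e-3,
)


def generate_incidence_table(
    shape: str = "constant", scale: float = 1e-3, age_max: int = 80
) -> pd.DataFrame:
    """Piecewise-constant incidence on 5-year bands from 0 to ``age_max``.

    ``shape="constant"`` gives every band the rate ``scale`` (per
    person-year).  ``shape="bc-like"`` gives a synthetic breast-cancer-
    like curve multiplied by ``scale`` (use ``scale=1.0`` for the preset
    itself, whose cumulative risk to 80 falls in the 5-15% range).
    """
    if scale <= 0:
        raise ConfigError(f"scale={scale} must be positive")
    if age_max <= 0 or age_max % 5 != 0:
        raise ConfigError(f"age_max={age_max} must be a positive multiple of 5")
    starts = np.arange(0, age_max, 5)
    if shape == "constant":
        rates = np.full(len(starts), scale)
    elif shape == "bc-like":
        base = np.array(_BC_LIKE_RATES)
        if len(starts) <= len(base):
            rates = base[: len(starts)] * scale
        else:
            rates = np.concatenate(
                [base, np.full(len(starts) - len(base), base[-1])]
            ) * scale
    else:
        raise ConfigError(f"unknown incidence shape {shape!r}")
    return pd.DataFrame(
        {"age_start": starts, "age_end": starts + 5, "rate_per_py": rates}
    )


# Synthetic stand-in domain intervals for the established genes
# (approximations of the real UniProt domains; adequate for exercising
# interval membership, not for biological interpretation).
_DEFAULT_DOMAINS = [
    ("ATM", "TAN", 1, 165),
    ("ATM", "FAT", 1960, 2566),
    ("ATM", "PI3K/PI4K_catalytic", 2712, 2962),
    ("ATM", "FATC", 3024, 3056),
    ("BRCA1", "Zinc-Finger", 24, 64),
    ("BRCA1", "BRCT1", 1662, 1723),
    ("BRCA1", "BRCT2", 1757, 1842),
    ("BRCA2", "BRC_repeats", 1002, 2085),
    ("BRCA2", "DNA-binding", 2481, 3186),
    ("CHEK2", "FHA", 113, 175),
    ("CHEK2", "kinase", 220, 486),
    ("PALB2", "RAD51-BRCA2-POLH_interaction", 1, 319),
    ("PALB2", "POLH_stimulation", 371, 561),
    ("PALB2", "WD1", 853, 892),
    ("PALB2", "WD2-WD7", 895, 1186),
    ("TP53", "DNA-binding", 94, 312),
    ("TP53", "tetramerization", 323, 356),
    ("BARD1", "RING", 49, 100),
    ("BARD1", "BRCT", 568, 777),
    ("RAD51C", "ATPase", 125, 376),
    ("RAD51D", "ATPase", 95, 328),
]


def default_domain_map() -> DomainMap:
    return DomainMap(
        pd.DataFrame(
            _DEFAULT_DOMAINS, columns=["gene", "domain", "residue_start", "residue_end"]
        )
    )


def write_tables(
    outdir,
    phenotypes: pd.DataFrame,
    variants: pd.DataFrame,
    domain_map: DomainMap | None = None,
    incidence: pd.DataFrame | None = None,
) -> dict:
    """Write the four input tables in their canonical text formats and
    return the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["phenotypes"] = outdir / "phenotypes.csv"
    phenotypes.to_csv(paths["phenotypes"], index=False)
    paths["variants"] = outdir / "variants.tsv"
    variants.to_csv(paths["variants"], sep="\t", index=False)
    if domain_map is not None:
        paths["domains"] = outdir / "domains.tsv"
        domain_map.to_tsv(paths["domains"])
    if incidence is not None:
        paths["incidence"] = outdir / "incidence.csv"
        incidence.to_csv(paths["incidence"], index=False)
    return {k: str(v) for k, v in paths.items()}
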