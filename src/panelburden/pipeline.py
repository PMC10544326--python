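"""End-to-end pipeline: generate/load -> classify -> tabulate ->
associate -> cumulative risk, with a manifest for reproducibility.

Driven by a single YAML config (see :class:`RunConfig`); identical
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    build_carrier_matrix,
    format_prevalence,
    stratify,
    tabulate_prevalence,
)
from .classify import (
    ClassificationConfig,
    DomainMap,
    ESTABLISHED_GENES,
    assign_domains_table,
    attrition_report,
    classify_table,
)
from .firth import DesignSpec, OUTCOMES, association_scan, fit_age_trend
from .risk import IncidenceTable, cumulative_risk_curve, threshold_report
from .simulate import CohortConfig, default_domain_map, generate_cohort, generate_incidence_table
from .validate import validate_frames

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("panelburden")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``inputs`` (paths to the four tables) or
    ``synthesize`` (a CohortConfig) must be given.
    """

    outdir: str
    seed: int = 0
    inputs: dict | None = None
    synthesize: CohortConfig | None = None
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    outcomes: tuple = OUTCOMES
    domain_scan: bool = True
    strata: tuple = ("family_history", "age_cut")
    age_trend_min_carriers: int = 5
    risk_p_threshold: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.inputs is None) == (self.synthesize is None):
            raise ValueError(
                "exactly one of 'inputs' and 'synthesize' must be configured"
            )
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        if bad:
            raise ValueError(f"unknown outcomes {bad}; expected subset of {OUTCOMES}")

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthesize" in raw and raw["synthesize"] is not None:
            syn = dict(raw["synthesize"])
            syn.setdefault("seed", raw.get("seed", 0))
            raw["synthesize"] = CohortConfig.from_dict(syn)
        if "classification" in raw and isinstance(raw["classification"], dict):
            cc = dict(raw["classification"])
            for key in ("panel_genes", "established_genes", "excluded_genes",
                        "penultimate_exception_genes"):
                if key in cc:
                    cc[key] = frozenset(cc[key])
            if "excluded_splice_hgvs" in cc:
                cc["excluded_splice_hgvs"] = frozenset(
                    (g, h) for g, h in cc["excluded_splice_hgvs"]
                )
            raw["classification"] = ClassificationConfig(**cc)
        for key in ("outcomes", "strata"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if hasattr(o, "__dict__"):
                return vars(o)
            if hasattr(o, "__dataclass_fields__"):
                return vars(o)
            return str(o)

        payload = {k: v for k, v in vars(self).items() if k not in ("outdir", "log_level")}
        blob = json.dumps(payload, default=default, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    phen = pd.read_csv(paths["phenotypes"])
    variants = pd.read_csv(paths["variants"], sep="\t")
    dm = DomainMap.from_tsv(paths["domains"]) if paths.get("domains") else default_domain_map()
    inc = (
        IncidenceTable.from_csv(paths["incidence"])
        if paths.get("incidence")
        else IncidenceTable(generate_incidence_table("bc-like", 1.0, 80))
    )
    return phen, variants, dm, inc


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write tables under ``cfg.outdir``.

    Returns the run manifest (also written as ``manifest.json``):
    config hash, seed, package version, and per-stage row counts.
    Any stage error aborts with a stage-tagged message.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
        "valid": False,
    }

    try:
        # ---- stage 1: inputs -------------------------------------------
        stage = "inputs"
        if cfg.synthesize is not None:
            phen, variants = generate_cohort(cfg.synthesize)
            dm = default_domain_map()
            inc = IncidenceTable(generate_incidence_table("bc-like", 1.0, 80))
            phen.to_csv(outdir / "phenotypes.csv", index=False)
            variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
            dm.to_tsv(outdir / "domains.tsv")
            inc.bands.to_csv(outdir / "incidence.csv", index=False)
        else:
            phen, variants, dm, inc = _load_inputs(cfg)
        report = validate_frames(phen, variants, dm.entries, inc.bands)
        report.raise_if_failed()
        manifest["stages"][stage] = {
            "subjects": int(len(phen)),
            "cases": int((phen["status"] == "case").sum()),
            "controls": int((phen["status"] == "control").sum()),
            "variant_rows": int(len(variants)),
        }
        log.info("inputs: %d subjects, %d variant rows", len(phen), len(variants))

        # ---- stage 2: classification -----------------------------------
        stage = "classify"
        classified = classify_table(variants, cfg.classification)
        classified = assign_domains_table(classified, dm)
        classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)
        att = attrition_report(classified)
        att.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
        counts = dict(zip(att["item"], att["rows"]))
        manifest["stages"][stage] = {k: int(v) for k, v in counts.items()}
        log.info("classified: %s", counts)

        # ---- stage 3: burden tabulation --------------------------------
        stage = "burden"
        gene_sets = {"established": sorted(cfg.classification.established_genes)}
        prevalences = {}
        matrices = {}
        for category in ("PTV", "RARE_MISSENSE"):
            cm = build_carrier_matrix(classified, phen, category, "gene")
            matrices[category] = cm
            prev = tabulate_prevalence(cm, phen, gene_sets)
            prevalences[category] = prev
            fname = f"prevalence_{category.lower()}.tsv"
            format_prevalence(prev).to_csv(outdir / fname, sep="\t", index=False)
        manifest["stages"][stage] = {
            cat: {"units": len(m.units), "carriers_any": int(m.indicator.to_numpy().any(axis=1).sum())}
            for cat, m in matrices.items()
        }

        # ---- stage 4: association scans --------------------------------
        stage = "associate"
        results = []
        for category, cm in matrices.items():
            specs = [DesignSpec(outcome=o) for o in cfg.outcomes]
            for res in association_scan(cm, phen, specs):
                results.append({**vars(res), "category": category, "unit_level": "gene"})
            for by in cfg.strata:
                parts, dropped = stratify(phen, by)
                log.info("stratifier %s: %s dropped", by, len(dropped))
                for name, ids in parts.items():
                    spec = DesignSpec(outcome="overall", stratum=(name, frozenset(ids)))
                    for res in association_scan(cm, phen, [spec]):
                        results.append({**vars(res), "category": category, "unit_level": "gene"})
        if cfg.domain_scan:
            cmd = build_carrier_matrix(
                classified[classified["gene"].isin(ESTABLISHED_GENES)], phen,
                "RARE_MISSENSE", "domain",
            )
            if cmd.units:
                specs = [DesignSpec(outcome=o) for o in cfg.outcomes]
                for res in association_scan(cmd, phen, specs):
                    results.append(
                        {**vars(res), "category": "RARE_MISSENSE", "unit_level": "domain"}
                    )
        assoc = pd.DataFrame(results)
        assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        n_failed = int((~assoc["converged"]).sum()) if len(assoc) else 0
        manifest["stages"][stage] = {"fits": int(len(assoc)), "not_converged": n_failed}
        if n_failed:
            log.warning("%d fits did not converge", n_failed)

        # ---- stage 5: age trends and cumulative risk -------------------
        stage = "risk"
        cm = matrices["PTV"]
        trends = []
        curves = {}
        overall = assoc[
            (assoc["category"] == "PTV")
            & (assoc["outcome"] == "overall")
            & (assoc["stratum"] == "")
        ]
        for _, row in overall.iterrows():
            unit = row["unit"]
            n_carr = int(cm.indicator[unit].sum())
            if n_carr >= cfg.age_trend_min_carriers:
                try:
                    tr = fit_age_trend(cm, phen, unit)
                    trends.append(
                        {
                            "unit": unit, "multiplier": tr.multiplier,
                            "ci_low": tr.ci_low, "ci_high": tr.ci_high, "p": tr.p,
                        }
                    )
                except (ValueError, np.linalg.LinAlgError) as exc:
                    log.warning("age trend for %s failed: %s", unit, exc)
            significant = (
                row["p_wald"] < cfg.risk_p_threshold and row["or_hat"] > 1.0
                and row["ci_low"] > 1.0
            )
            if significant:
                n_ctrl = int((phen["status"] == "control").sum())
                f_hat = cm.indicator.loc[
                    phen.loc[phen["status"] == "control", "subject_id"], unit
                ].sum() / max(n_ctrl, 1)
                curve = cumulative_risk_curve(
                    or_hat=float(row["or_hat"]), inc=inc, f=float(f_hat),
                    ci=(float(row["ci_low"]), float(row["ci_high"])), label=unit,
                )
                curves[unit] = curve
        pd.DataFrame(trends).to_csv(outdir / "age_trends.tsv", sep="\t", index=False)
        if curves:
            pd.concat(
                [c.frame().assign(unit=u) for u, c in curves.items()]
            ).to_csv(outdir / "risk_curves.tsv", sep="\t", index=False)
            threshold_report(curves).to_csv(
                outdir / "risk_thresholds.tsv", sep="\t", index=False
            )
        manifest["stages"][stage] = {"age_trends": len(trends), "risk_curves": len(curves)}

        manifest["valid"] = True
    except Exception as exc:
        manifest["error"] = f"stage '{stage}' failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(manifest["error"]) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.removeHandler(handler)
    handler.close()
    return manifest
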