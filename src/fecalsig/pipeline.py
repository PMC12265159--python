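"""End-to-end pipeline: simulate (optional) -> methylation profiling ->
ddPCR quantification -> host fraction -> clinical harmonization ->
ecology -> models, with a manifest recording seeds, thresholds and
per-stage sample attrition."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import synthio, methylprofile, ddpcr, hostfrac, inflammetrics, ecology, models

log = logging.getLogger("fecalsig")

STAGES = (
    "simulate", "methylprofile", "ddpcr", "hostfrac",
    "inflammetrics", "ecology", "models",
)


@dataclass
class PipelineConfig:
    outdir: str = "fecalsig_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides
    min_similarity: float = 80.0
    min_reads: int = 1000
    sum_bounds: tuple[float, float] = (5.0, 150.0)
    calprotectin_cap: float = 2100.0
    human_threshold: float = 1.0
    subsample_depth: int = 1_000_000
    alpha: float = 0.05
    run_models: bool = True
    run_subsample: bool = False  # 1M-depth control; heavy, off by default
    classifier_nrounds: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.sum_bounds, list):
            cfg.sum_bounds = tuple(cfg.sum_bounds)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sum_bounds"] = list(self.sum_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage on a simulated cohort and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": [],
        "attrition": [],
        "warnings": [],
    }

    try:
        # --- simulate ----------------------------------------------------
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        cohort_cfg = synthio.CohortConfig(**sim_kwargs)
        cohort = synthio.simulate_cohort(cohort_cfg)
        cohort.write(outdir / "dataset")
        n0 = len(cohort.clinical)
        manifest["stages"].append("simulate")
        log.info("simulated %d samples", n0)

        # --- ddPCR -------------------------------------------------------
        quant = ddpcr.quantify_table(cohort.droplets)
        quant.to_csv(outdir / "ddpcr_quant.tsv", sep="\t", index=False)
        human_pct = quant.set_index("sample_id")["human_pct"]
        n_sat = int(quant["saturated"].sum())
        if n_sat:
            manifest["warnings"].append({"stage": "ddpcr", "saturated": n_sat})
        manifest["stages"].append("ddpcr")

        # --- methylation profiling ---------------------------------------
        profiles = []
        for sid, reads in cohort.reads.items():
            profiles.append(
                methylprofile.aggregate_sample(
                    reads, cohort.panel,
                    ddpcr_human_pct=float(human_pct[sid]),
                    sample_id=sid,
                    min_similarity=config.min_similarity,
                    min_reads=config.min_reads,
                    sum_bounds=config.sum_bounds,
                )
            )
        prof_df = methylprofile.profiles_to_frame(profiles)
        prof_df.to_csv(outdir / "methylprofiles.tsv", sep="\t", index=False)
        kept = [p for p in profiles if p.qc_pass]
        manifest["attrition"].append(
            {"stage": "methylprofile", "in": len(profiles), "out": len(kept),
             "excluded": len(profiles) - len(kept)}
        )
        manifest["stages"].append("methylprofile")

        # --- host fraction -----------------------------------------------
        rc = cohort.read_counts
        meta_pct = pd.Series(
            100.0 * rc["human_reads"] / rc["total_reads"], index=rc["sample_id"].values
        )
        tax = hostfrac.TaxProfile(
            matrix=cohort.species_pct, read_counts=cohort.read_counts
        )
        manifest["stages"].append("hostfrac")
        if config.run_subsample:
            sub, rep = hostfrac.subsample_nonhuman(
                tax, depth=config.subsample_depth, seed=config.seed
            )
            manifest["attrition"].append(
                {"stage": "subsample", "in": len(tax.samples),
                 "out": len(sub.samples), "excluded": len(rep.dropped_samples)}
            )

        # --- clinical harmonization + inflammation metrics ----------------
        clinical = inflammetrics.harmonize_table(
            cohort.clinical, cap=config.calprotectin_cap
        )
        clinical["human_pct"] = clinical["sample_id"].map(human_pct)
        clinical["human_reads_pct"] = clinical["sample_id"].map(meta_pct)
        by_prof = {p.sample_id: p for p in profiles}
        clinical["nlr"] = [
            inflammetrics.nlr(by_prof[s]) if s in by_prof else np.nan
            for s in clinical["sample_id"]
        ]
        clinical["ner"] = [
            inflammetrics.ner(by_prof[s]) if s in by_prof else np.nan
            for s in clinical["sample_id"]
        ]
        clinical.to_csv(outdir / "clinical_harmonized.tsv", sep="\t", index=False)
        high = inflammetrics.high_human_fraction(
            clinical, threshold=config.human_threshold
        )
        high.to_csv(outdir / "high_human_fraction.tsv", sep="\t", index=False)
        manifest["stages"].append("inflammetrics")

        # --- ecology ------------------------------------------------------
        groups = clinical.set_index("sample_id")["group"]
        richness = pd.DataFrame(
            {
                "sample_id": tax.samples,
                "species_count": [
                    ecology.species_count(tax.matrix[s]) for s in tax.samples
                ],
                "shannon": [ecology.shannon(tax.matrix[s]) for s in tax.samples],
            }
        )
        richness.to_csv(outdir / "richness.tsv", sep="\t", index=False)
        ord_res = ecology.rclr_pcoa(tax.matrix, n_components=10)
        ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        cats = ecology.classify_species(tax.matrix, groups, alpha=config.alpha)
        cats.to_csv(outdir / "species_categories.tsv", sep="\t")
        curve = ecology.group_median_curve(tax.matrix, groups)
        curve.to_csv(outdir / "group_median_curve.tsv", sep="\t")
        manifest["stages"].append("ecology")

        # --- models -------------------------------------------------------
        if config.run_models:
            cl = clinical.set_index("sample_id")
            lmm = models.fit_calprotectin_lmm(clinical)
            lmm.params.to_csv(outdir / "lmm_coefficients.tsv", sep="\t")
            y = (groups != "Control").astype(int)
            spec = models.ClassifierSpec(
                task="ControlVsIBD", seed=config.seed,
                nrounds=config.classifier_nrounds,
            )
            X = models.build_features(
                tax.matrix, "presence_absence",
                ("species", "species_count", "human_reads_pct"),
                human_reads_pct=cl["human_reads_pct"],
            )
            cv = models.train_cv_classifier(X, y.loc[X.index], spec)
            cv.roc.to_csv(outdir / "roc_control_vs_ibd.tsv", sep="\t", index=False)
            imp = models.feature_importance(cv)
            imp.to_csv(outdir / "feature_importance.tsv", sep="\t")
            manifest["model_summary"] = {
                "cv_auc": cv.auc,
                "best_round": cv.best_round,
                "lmm_r2_marginal": lmm.r2_marginal,
                "lmm_r2_conditional": lmm.r2_conditional,
                "lmm_treatment_beta": lmm.coef("treatment_advancement"),
            }
            manifest["stages"].append("models")
        else:
            manifest["stages"].append("models")

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
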