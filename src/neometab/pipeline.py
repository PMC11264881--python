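"""Configuration-driven end-to-end runner.

Ties simulate -> normalize -> process -> mwas -> pcorr/enrich (and the
optional adult-cohort gwas/phewas stages) together, with a manifest
recording every software decision taken (imputation method, LOESS span,
FDR procedure, boundary rules, per-stage seeds) so a run is auditable and
any single stage can be reproduced from the manifest.

A single global seed is expanded with a counter-based scheme
(``SeedSequence([seed, stage_counter])``) into per-stage seeds, so adding or
toggling a stage never reshuffles the randomness of the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment_network, feature_processing, genetics_scan
from . import io_model, qc_normalization, synthetic_data
from .io_model import ConfigError

__all__ = ["load_config", "run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "normalize", "process", "mwas", "pcorr", "enrich", "gwas", "phewas")
_STAGE_SEED = {name: i for i, name in enumerate(_STAGES)}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_pairs": 200,
        "n_features": 100,
        "n_plates": 4,
        "drift_amplitude": 0.2,
        "batch_sd": 0.1,
        "signal_features": [
            {"feature_id": "F0001", "mode": "continuous", "true_or": 2.0},
            {"feature_id": "F0002", "mode": "binary", "true_or": 3.0},
        ],
    },
    "normalize": {"enabled": True, "span": 2.0 / 3.0, "degree": 1, "per_plate": True},
    "process": {
        "low_threshold": 0.25,
        "high_threshold": 0.75,
        "impute_method": "tree",
        "batch_method": "plate_median",
    },
    "mwas": {"model": 1, "fdr": 0.05, "stratify_age": False},
    "pcorr": {"enabled": True, "mode": "ridge", "top_k": 20},
    "enrich": {"enabled": False, "class_labels": None},
    "gwas": {"enabled": False, "n": 1500, "n_snps": 300,
             "causal": [["rs000001", 0.024]], "diet_corr": 0.18},
    "phewas": {"enabled": False, "folds": 10},
}


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _STAGE_SEED[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(_STAGES) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown pipeline stage(s): {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sim_config(cfg: dict, seed: int) -> synthetic_data.SimConfig:
    sim = dict(cfg["simulate"])
    signals = [
        synthetic_data.SignalFeature(s["feature_id"], s["mode"], float(s["true_or"]))
        for s in sim.pop("signal_features", [])
    ]
    return synthetic_data.SimConfig(seed=seed, signal_features=signals, **sim)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages; returns a dict of artifact paths.

    Deterministic given the global seed; partial outputs are retained if a
    stage fails (the error is re-raised annotated with the stage name).
    """
    unknown = set(config) - set(_STAGES) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown pipeline stage(s): {sorted(unknown)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    logging.getLogger("neometab").addHandler(handler)
    logging.getLogger("neometab").setLevel(logging.INFO)

    manifest: dict = {"seed": config["seed"], "stages": {}, "decisions": {
        "fdr_procedure": "Benjamini-Hochberg step-up across all tested features",
        "partition_boundaries": "presence < 0.25 dropped; < 0.75 binary; >= 0.75 continuous",
        "logistic_model": "unconditional ML logistic adjusted for matching factors; Wald CI/p",
        "stage_order": "impute -> batch-correct -> standardize for continuous features",
    }}
    artifacts: dict = {"outdir": str(out)}
    stage = "simulate"
    try:
        # ------------------------------------------------ simulate
        seed = _stage_seed(config["seed"], "simulate")
        sim_cfg = _sim_config(config, seed)
        records, truth = synthetic_data.generate_neonatal_cohort(sim_cfg)
        table = synthetic_data.generate_feature_matrix(records, truth, sim_cfg)
        io_model.write_sample_records(records, out / "samples.tsv")
        io_model.write_feature_table(table, out / "features_raw.tsv", out / "sample_metadata.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "effects": truth.effects,
                    "presence_targets": truth.presence_targets,
                    "expected_stratum": truth.expected_stratum,
                },
                fh, indent=1,
            )
        manifest["stages"]["simulate"] = {"seed": seed, "n_pairs": sim_cfg.n_pairs,
                                          "n_features": sim_cfg.n_features}
        artifacts["features_raw"] = str(out / "features_raw.tsv")

        # ------------------------------------------------ normalize
        stage = "normalize"
        ncfg = config["normalize"]
        if ncfg.get("enabled", True):
            model = qc_normalization.fit_drift_model(
                table, span=ncfg["span"], degree=ncfg["degree"], per_plate=ncfg["per_plate"]
            )
            rsd_pre = qc_normalization.qc_report(table)["rsd"].mean()
            table = qc_normalization.apply_drift_correction(table, model)
            rsd_post = qc_normalization.qc_report(table)["rsd"].mean()
            manifest["stages"]["normalize"] = {
                "span": ncfg["span"], "degree": ncfg["degree"], "per_plate": ncfg["per_plate"],
                "mean_qc_rsd_pre": float(rsd_pre), "mean_qc_rsd_post": float(rsd_post),
                "n_skipped": len(model.skipped),
            }
            io_model.write_feature_table(
                table, out / "features_normalized.tsv", out / "sample_metadata.tsv"
            )
            artifacts["features_normalized"] = str(out / "features_normalized.tsv")

        # ------------------------------------------------ process
        stage = "process"
        pcfg = config["process"]
        processed = feature_processing.process_features(
            table,
            feature_processing.PartitionConfig(pcfg["low_threshold"], pcfg["high_threshold"]),
            impute_method=pcfg["impute_method"],
            batch_method=pcfg["batch_method"],
            seed=_stage_seed(config["seed"], "process"),
        )
        processed.stratum.rename("stratum").to_csv(out / "strata.tsv", sep="\t")
        manifest["stages"]["process"] = dict(processed.metadata)
        artifacts["strata"] = str(out / "strata.tsv")

        # ------------------------------------------------ mwas
        stage = "mwas"
        mcfg = config["mwas"]
        samples_df = io_model.records_to_frame(records)
        spec = association.ModelSpec.model2() if mcfg["model"] == 2 else association.ModelSpec.model1()
        results = association.run_mwas(processed, samples_df, spec)
        io_model.write_assoc_results(results, out / "assoc.tsv")
        manifest["stages"]["mwas"] = {
            "model": spec.model_id,
            "n_tested": len(results),
            "n_fdr_significant": int(sum(r.q < mcfg["fdr"] for r in results)),
        }
        artifacts["assoc"] = str(out / "assoc.tsv")
        if mcfg.get("stratify_age", False):
            strat = association.stratified_interaction(processed, samples_df)
            strat.to_csv(out / "assoc_stratified.tsv", sep="\t")
            artifacts["assoc_stratified"] = str(out / "assoc_stratified.tsv")

        # ------------------------------------------------ pcorr
        stage = "pcorr"
        ccfg = config["pcorr"]
        if ccfg.get("enabled", True) and len(processed.continuous.columns) >= 2:
            by_p = sorted(
                (r for r in results if r.mode == "continuous_per_sd"), key=lambda r: r.p
            )
            top = [r.feature_id for r in by_p[: ccfg["top_k"]]]
            pc = enrichment_network.partial_corr_matrix(
                processed.continuous[top], mode=ccfg["mode"]
            )
            edges = pd.DataFrame(
                [(e.i, e.j, e.rho, e.p) for e in pc.pairs()],
                columns=["feature_i", "feature_j", "rho", "p"],
            )
            edges.to_csv(out / "pcorr_edges.tsv", sep="\t", index=False)
            manifest["stages"]["pcorr"] = {"mode": pc.mode, "n_features": len(top)}
            artifacts["pcorr_edges"] = str(out / "pcorr_edges.tsv")

        # ------------------------------------------------ enrich
        stage = "enrich"
        ecfg = config["enrich"]
        if ecfg.get("enabled", False) and ecfg.get("class_labels"):
            labels = pd.read_csv(ecfg["class_labels"], sep="\t", index_col=0).iloc[:, 0]
            sig = pd.Series({r.feature_id: r.p < 0.05 for r in results})
            enr = enrichment_network.class_enrichment(sig, labels)
            pd.DataFrame([asdict(e) for e in enr]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {"n_classes": len(enr)}
            artifacts["enrichment"] = str(out / "enrichment.tsv")

        # ------------------------------------------------ gwas / phewas
        stage = "gwas"
        gcfg = config["gwas"]
        if gcfg.get("enabled", False):
            cohort = synthetic_data.generate_adult_cohort(
                n=gcfg["n"], n_snps=gcfg["n_snps"],
                causal=[(s, float(v)) for s, v in gcfg.get("causal", [])],
                diet_corr=float(gcfg.get("diet_corr", 0.0)),
                seed=_stage_seed(config["seed"], "gwas"),
            )
            assoc = genetics_scan.gwas_scan(
                cohort.genotypes, cohort.metabolite, cohort.phenotypes[["age", "sex"]]
            )
            assoc.to_csv(out / "gwas.assoc.tsv", sep="\t", index=False)
            manifest["stages"]["gwas"] = {
                "n": gcfg["n"], "n_snps": gcfg["n_snps"],
                "lambda_gc": genetics_scan.lambda_gc(
                    assoc.loc[~assoc.SNP.isin(cohort.truth.causal_snps), "P"]
                ),
            }
            artifacts["gwas"] = str(out / "gwas.assoc.tsv")

            stage = "phewas"
            fcfg = config["phewas"]
            if fcfg.get("enabled", False):
                predictors = pd.concat([cohort.phenotypes, cohort.genotypes], axis=1)
                res = genetics_scan.lasso_phewas(
                    cohort.metabolite, predictors,
                    genetics_scan.LassoConfig(
                        folds=fcfg.get("folds", 10),
                        seed=_stage_seed(config["seed"], "phewas"),
                    ),
                )
                res.coefficients.rename("coefficient").to_csv(out / "phewas.tsv", sep="\t")
                manifest["stages"]["phewas"] = {"alpha": res.alpha, "cv_r2": res.cv_r2,
                                                "top": res.ranking[:30]}
                artifacts["phewas"] = str(out / "phewas.tsv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        logging.getLogger("neometab").removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    artifacts["manifest"] = str(out / "manifest.json")
    logging.getLogger("neometab").removeHandler(handler)
    handler.close()
    return artifacts
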