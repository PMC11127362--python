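"""End-to-end pipeline driver.

Stage order mirrors the discovery cascade: simulate (optional) ->
phenotype from SCFA -> differential abundance per substrate ->
substrate-specific gene filter -> cluster detection -> whole-cluster
selection -> qPCR quantification -> feature ranking -> classifier
training -> prediction.  Every stage is seeded from the master seed and
the emitted artifact bundle is byte-identical across runs with the same
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cgc, da, io, ml, phenotyping, qpcr, synthetic

logger = logging.getLogger("prebioresponse")


@dataclass
class PipelineConfig:
    """Master configuration: one sub-config per stage plus the seed."""

    sim: synthetic.SimParams = field(default_factory=synthetic.SimParams)
    analysis: phenotyping.AnalysisConfig = field(
        default_factory=phenotyping.AnalysisConfig
    )
    cgc_params: cgc.CgcParams = field(default_factory=cgc.CgcParams)
    # desk-scale resampling defaults; heavier settings are a config edit away
    svm: ml.SvmConfig = field(
        default_factory=lambda: ml.SvmConfig(cv_repeats=3, n_models=10)
    )
    da_q_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        seed = int(raw.get("seed", 0))
        sim = synthetic.SimParams(**{**raw.get("sim", {}), "seed": seed})
        analysis = phenotyping.AnalysisConfig(**raw.get("analysis", {}))
        cgc_params = cgc.CgcParams(**raw.get("cgc", {}))
        svm_kwargs = dict(cv_repeats=3, n_models=10)
        svm_kwargs.update(raw.get("svm", {}))
        svm = ml.SvmConfig(**{**svm_kwargs, "seed": seed})
        return cls(
            sim=sim,
            analysis=analysis,
            cgc_params=cgc_params,
            svm=svm,
            da_q_threshold=float(raw.get("da_q_threshold", 0.05)),
            seed=seed,
        )


def load_config(path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


def quantify_copy_numbers(
    wells: pd.DataFrame, standards: pd.DataFrame
) -> pd.DataFrame:
    """Fit a standard curve per target gene and quantify every well.

    Replicate wells are averaged on the copy scale; non-detect wells
    contribute 0 copies.  Returns subjects x target-genes copy numbers.
    """
    curves = {
        g: qpcr.fit_standard_curve(grp["copies"], grp["ct"])
        for g, grp in standards.groupby("target_gene")
    }
    rows = []
    for (sample, gene), grp in wells.groupby(["sample_id", "target_gene"]):
        copies = []
        for ct in grp["ct"]:
            if pd.isna(ct):
                copies.append(0.0)
            else:
                c, _ = qpcr.quantify_unknown(curves[gene], float(ct))
                copies.append(c)
        rows.append({"sample_id": sample, "target_gene": gene,
                     "copies": float(np.mean(copies))})
    out = pd.DataFrame(rows).pivot(
        index="sample_id", columns="target_gene", values="copies"
    )
    out.index.name = "subject_id"
    return out


def classifier_auc_benchmark(
    seeds,
    base_params: synthetic.SimParams | None = None,
    svm_config: ml.SvmConfig | None = None,
) -> pd.DataFrame:
    """Held-out AUC of the per-substrate responder classifier per seed.

    For every generator seed: simulate the cohort's gene catalog and
    baseline qPCR screen, quantify copy numbers through the standard
    curves, split subjects 50:50 stratified by the planted phenotype,
    grid-search an RBF SVM on the training half and score the held-out
    half.  Returns one row per (seed, substrate) with the test AUC.
    """
    base_params = base_params or synthetic.SimParams()
    rows = []
    for seed in seeds:
        params = synthetic.SimParams(**{**base_params.__dict__, "seed": int(seed)})
        catalog, truth = synthetic.simulate_gene_catalog(params)
        _copies_true, wells, standards = synthetic.simulate_qpcr(truth, params)
        copies = quantify_copy_numbers(wells, standards)
        cfg = svm_config or ml.SvmConfig(cv_repeats=10, seed=int(seed))
        for substrate in params.substrates:
            targets = [
                g for g in truth.planted_genes.get(substrate, [])
                if g in copies.columns
            ] + [g for g in truth.decoy_genes if g in copies.columns]
            X, y = ml.build_feature_matrix(copies[targets], truth.phenotype[substrate])
            X_tr, y_tr, X_te, y_te = ml.split_train_test(
                X, y, fraction=cfg.split_fraction, seed=int(seed)
            )
            model = ml.train_svm(X_tr, y_tr, cfg, seed=int(seed))
            rows.append(
                {
                    "seed": int(seed),
                    "substrate": substrate,
                    "test_auc": ml.auc(y_te, model.decision_scores(X_te)),
                    "cv_auc": model.cv_auc,
                    "n_test": len(y_te),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full discovery-and-prediction cascade on a synthetic cohort.

    Writes the artifact bundle (scfa.tsv, catalog.gff3/tsv, counts.tsv,
    qpcr wells/standards, truth.json, phenotypes.tsv, diagnostics.tsv,
    da_<substrate>.tsv, cgcs.tsv, selected_cgcs.tsv, importance_*.tsv,
    models.json, predictions_*.tsv, report.json) and returns the bundle
    in memory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort = synthetic.simulate_cohort(config.sim)
        truth = cohort["truth"]
        io.write_tsv(cohort["scfa"], outdir / "scfa.tsv")
        io.write_catalog_gff3(cohort["catalog"], outdir / "catalog.gff3")
        io.write_tsv(cohort["catalog"], outdir / "catalog.tsv")
        io.write_tsv(cohort["counts"].reset_index(), outdir / "counts.tsv")
        io.write_tsv(cohort["samples"], outdir / "samples.tsv")
        io.write_qpcr_wells(cohort["wells"], outdir / "qpcr_wells.tsv")
        io.write_tsv(cohort["standards"], outdir / "qpcr_standards.tsv")
        io.write_truth(truth, outdir / "truth.json")
        logger.info("simulate: %d scfa records, %d genes, %d samples",
                    len(cohort["scfa"]), len(cohort["catalog"]),
                    len(cohort["samples"]))

        stage = "phenotype"
        calls = phenotyping.assign_phenotypes(cohort["scfa"], config.analysis)
        diagnostics = phenotyping.phenotype_diagnostics(
            cohort["scfa"], config.analysis
        )
        io.write_tsv(calls, outdir / "phenotypes.tsv")
        io.write_tsv(diagnostics, outdir / "diagnostics.tsv")
        logger.info("phenotype: %d calls, %d responders", len(calls),
                    int((calls["label"] == "R").sum()))

        stage = "find-cgc"
        cgcs = cgc.find_cgcs(cohort["catalog"], config.cgc_params)
        cgc_out = cgcs.copy()
        cgc_out["member_gene_ids"] = cgc_out["member_gene_ids"].map(",".join)
        io.write_tsv(cgc_out, outdir / "cgcs.tsv")

        call_map = calls.set_index(["subject_id", "substrate"])["label"]
        da_results: dict[str, pd.DataFrame] = {}
        selected_frames = []
        for substrate in config.sim.substrates:
            stage = f"da-test[{substrate}]"
            meta = cohort["samples"]
            meta_s = meta[meta["substrate"] == substrate]
            labels = [
                call_map.loc[(subj, substrate)] for subj in meta_s["subject_id"]
            ]
            counts_s = cohort["counts"][meta_s["sample_id"]]
            res = da.nb_wald_test(counts_s, labels)
            da_results[substrate] = res
            io.write_tsv(res.reset_index(names="gene_id"),
                         outdir / f"da_{substrate}.tsv")

            stage = f"substrate-filter[{substrate}]"
            annotated = cohort["catalog"].set_index("gene_id").join(res, how="inner")
            spec = cgc.SubstrateSpec.default(substrate)
            filtered = cgc.substrate_gene_filter(
                annotated.reset_index(), spec
            ).set_index("gene_id")
            retained = cgc.responder_association_filter(
                filtered, q_threshold=config.da_q_threshold
            )
            selected, singletons = cgc.clusters_for_genes(retained, cgcs, substrate)
            if singletons:
                logger.warning("%s: %d retained genes outside any cluster",
                               substrate, len(singletons))
            if not selected.empty:
                selected_frames.append(selected)
            logger.info("%s: %d retained genes, %d selected clusters",
                        substrate, len(retained), len(selected))
        selected_all = (
            pd.concat(selected_frames, ignore_index=True)
            if selected_frames
            else pd.DataFrame(columns=["cgc_id", "substrate", "member_gene_ids"])
        )
        sel_out = selected_all.copy()
        if not sel_out.empty:
            sel_out["member_gene_ids"] = sel_out["member_gene_ids"].map(",".join)
        io.write_tsv(sel_out, outdir / "selected_cgcs.tsv")

        stage = "quantify"
        copy_numbers = quantify_copy_numbers(cohort["wells"], cohort["standards"])
        io.write_tsv(copy_numbers.reset_index(), outdir / "copy_numbers.tsv")

        stage = "rank-features"
        importance: dict[str, pd.DataFrame] = {}
        models: dict[str, ml.TrainedModel] = {}
        predictions: dict[str, pd.DataFrame] = {}
        model_meta = {}
        for substrate in config.sim.substrates:
            targets = [
                g
                for g in truth.planted_genes.get(substrate, [])
                if g in copy_numbers.columns
            ] + [g for g in truth.decoy_genes if g in copy_numbers.columns]
            if not targets:
                continue
            X, y = ml.build_feature_matrix(
                copy_numbers[targets],
                call_map.xs(substrate, level="substrate"),
            )
            imp = ml.permutation_importance(X, y, config.svm)
            importance[substrate] = imp
            imp_out = imp.drop(columns="per_model_delta")
            io.write_tsv(imp_out, outdir / f"importance_{substrate}.tsv")

            stage = f"train[{substrate}]"
            X_tr, y_tr, X_te, y_te = ml.split_train_test(
                X, y, fraction=config.svm.split_fraction, seed=config.seed
            )
            model = ml.train_svm(X_tr, y_tr, config.svm, seed=config.seed)
            models[substrate] = model
            test_auc = ml.auc(y_te, model.decision_scores(X_te))
            model_meta[substrate] = {
                "C": model.C,
                "sigma": model.sigma,
                "cv_auc": round(model.cv_auc, 6),
                "test_auc": round(test_auc, 6),
                "features": model.feature_names,
                "scale_mean": [round(v, 9) for v in model.scale_mean],
                "scale_std": [round(v, 9) for v in model.scale_std],
            }

            stage = f"predict[{substrate}]"
            pred = ml.predict_phenotype(model, X)
            predictions[substrate] = pred
            io.write_tsv(pred.reset_index(), outdir / f"predictions_{substrate}.tsv")

        (outdir / "models.json").write_text(
            json.dumps(model_meta, indent=1, sort_keys=True) + "\n"
        )

        report = {
            "seed": config.seed,
            "n_subjects": config.sim.n_subjects,
            "n_genes": len(cohort["catalog"]),
            "n_cgcs": len(cgcs),
            "n_selected_cgcs": len(selected_all),
            "responders_per_substrate": {
                s: int(
                    (calls[calls["substrate"] == s]["label"] == "R").sum()
                )
                for s in config.sim.substrates
            },
            "test_auc": {s: m["test_auc"] for s, m in model_meta.items()},
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "cohort": cohort,
        "phenotypes": calls,
        "cgcs": cgcs,
        "selected_cgcs": selected_all,
        "da": da_results,
        "copy_numbers": copy_numbers,
        "importance": importance,
        "models": models,
        "predictions": predictions,
        "report": report,
    }
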