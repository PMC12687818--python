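"""End-to-end pipeline: simulate -> label -> prep -> train -> evaluate ->
interpret -> network.

Each stage draws its randomness from a seed derived from the global seed by
stage name, logs its row/feature counts, and (when an output directory is
given) writes its artifact next to the resolved configuration, so a run is
reproducible and each stage can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cjs, features, interpret, io, metrics, model, network, simulate
from .config import RunConfig

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("hybridsurv")


@dataclass
class PipelineResult:
    config: RunConfig
    traits: pd.DataFrame
    detections: pd.DataFrame
    labels: pd.DataFrame
    prepared: features.PreparedFeatures
    bundle: model.ModelBundle
    report: metrics.MetricsReport
    curve: metrics.ThresholdCurve
    importance: interpret.ImportanceReport
    interactions: interpret.InteractionScreen
    shap: interpret.ShapMatrix
    trait_network: network.CorrelationNetwork
    label_agreement: float | None = None


def _stage(name: str, **counts):
    info = ", ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s %s", name, info)


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute every stage on a synthetic cohort and return all artifacts.

    A failure in any stage propagates with the stage name attached.  With
    ``outdir`` set, CSV/JSON artifacts and the resolved config are written
    there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    seeds = config.stage_seeds

    stage = "simulate"
    try:
        sim_cfg = simulate.SimConfig(
            n_birds=config.n_birds,
            n_loci=config.n_loci,
            base_survival_rate=config.base_survival_rate,
            detection_prob=config.detection_prob,
            missing_frac_behaviour=config.missing_frac_behaviour,
            seed=seeds["simulate"],
            study_days=config.study_days,
            occasion_days=config.occasion_days,
        )
        birds, traits, detections = simulate.generate_cohort(sim_cfg)
        _stage(stage, seed=seeds["simulate"], birds=len(traits), detections=len(detections))
        if out is not None:
            io.write_traits(traits, out / "traits.csv", seed=seeds["simulate"])
            io.write_detections(detections, out / "detections.csv", seed=seeds["simulate"])

        stage = "label"
        groups = dict(tuple(detections.groupby("bird_id")))
        histories = np.stack(
            [
                cjs.bin_detections(
                    groups[b]["days_since_tag"].to_numpy() if b in groups else [],
                    study_days=config.study_days,
                    occasion_days=config.occasion_days,
                )
                for b in traits["bird_id"]
            ]
        )
        probs, y_labels, fit = cjs.label_cohort(histories, mode=config.cjs_mode)
        labels = pd.DataFrame(
            {"bird_id": traits["bird_id"], "overall_survival_prob": probs, "label": y_labels}
        )
        agreement = None
        if "survived_true" in traits.columns:
            agreement = float(np.mean(y_labels == traits["survived_true"].to_numpy()))
        _stage(stage, seed=seeds["label"], birds=len(labels),
               survivor_frac=round(float(y_labels.mean()), 4))
        if out is not None:
            io.write_labels(labels, out / "labels.csv", seed=seeds["label"])

        stage = "prep"
        candidates = features.build_feature_matrix(traits, detections)
        prepared = features.prepare_features(
            candidates,
            y_labels,
            mode=config.mode,
            test_frac=config.test_frac,
            seed=seeds["prep"],
            corr_threshold=config.corr_threshold,
            max_missing=config.max_missing,
            k_impute=config.k_impute,
        )
        _stage(stage, seed=seeds["prep"], features=len(prepared.feature_names),
               train=len(prepared.y_train), test=len(prepared.y_test))
        if out is not None:
            mat = prepared.X_train.copy()
            mat.to_csv(out / "feature_matrix_train.csv")
            prepared.X_test.to_csv(out / "feature_matrix_test.csv")

        stage = "train"
        best_cfg, cv_table = model.tune_hyperparameters(
            prepared.X_train.to_numpy(),
            prepared.y_train,
            n_candidates=config.n_candidates,
            seed=seeds["train"],
            n_splits=config.cv_folds,
            smote_k=config.smote_k,
        )
        Xb, yb, _ = model.smote(
            prepared.X_train.to_numpy(), prepared.y_train,
            model.SmoteConfig(k_neighbors=config.smote_k, seed=seeds["train"]),
        )
        forest = model.train_forest(Xb, yb, best_cfg)
        bundle = model.ModelBundle(
            forest=forest, config=best_cfg, cv_table=cv_table,
            feature_names=prepared.feature_names, seed=seeds["train"],
        )
        _stage(stage, seed=seeds["train"], candidates=len(cv_table),
               best=best_cfg.n_estimators)

        stage = "evaluate"
        probs_test = forest.predict_proba(prepared.X_test.to_numpy())[:, 1]
        curve = metrics.threshold_sweep(probs_test, prepared.y_test)
        bundle.threshold = curve.optimal
        y_pred = (probs_test >= bundle.threshold).astype(int)
        report = metrics.class_metrics(metrics.confusion(prepared.y_test, y_pred))
        report.brier = metrics.brier(probs_test, prepared.y_test)
        report.threshold = bundle.threshold
        _stage(stage, seed=seeds["evaluate"], accuracy=round(report.accuracy, 4),
               macro_f1=round(report.macro_f1, 4), threshold=round(bundle.threshold, 4))
        if out is not None:
            with open(out / "metrics.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "accuracy": report.accuracy,
                        "precision": {str(k): v for k, v in report.precision.items()},
                        "recall": {str(k): v for k, v in report.recall.items()},
                        "f1": {str(k): v for k, v in report.f1.items()},
                        "specificity": report.specificity,
                        "macro_f1": report.macro_f1,
                        "brier": report.brier,
                        "threshold": report.threshold,
                    },
                    fh,
                    indent=2,
                )
            pd.DataFrame({"threshold": curve.grid, "macro_f1": curve.macro_f1}).to_csv(
                out / "threshold_curve.csv", index=False
            )

        stage = "interpret"
        importance = interpret.gini_importance(forest, prepared.feature_names)
        interactions = interpret.interaction_screen(
            bundle,
            prepared.X_test.to_numpy(),
            prepared.y_test,
            feature_names=prepared.feature_names,
            n_repeats=config.interaction_repeats,
            seed=seeds["interpret"],
            cutoff=config.delta_f1_cutoff,
        )
        shap_matrix = interpret.shap_dependence(
            bundle, prepared.X_train.to_numpy(),
            max_background=config.shap_background, seed=seeds["interpret"],
        )
        _stage(stage, seed=seeds["interpret"], pairs=len(interactions.pairs),
               retained=len(interactions.retained))
        if out is not None:
            importance.to_frame().to_csv(out / "importance.csv", index=False)
            interactions.to_frame().to_csv(out / "interactions.csv", index=False)
            shap_matrix.to_frame().to_csv(out / "shap_values.csv", index=False)

        stage = "network"
        panel = candidates[prepared.feature_names]  # pre-imputation values
        net = network.bootstrap_network(
            panel, n_boot=config.n_boot, alpha=config.network_alpha, seed=seeds["network"]
        )
        _stage(stage, seed=seeds["network"],
               edges=int(net.edges["significant"].sum()))
        if out is not None:
            net.edges.to_csv(out / "network_edges.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    return PipelineResult(
        config=config, traits=traits, detections=detections, labels=labels,
        prepared=prepared, bundle=bundle, report=report, curve=curve,
        importance=importance, interactions=interactions, shap=shap_matrix,
        trait_network=net, label_agreement=agreement,
    )
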