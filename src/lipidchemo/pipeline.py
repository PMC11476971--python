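"""End-to-end orchestration of the discrimination workflow.

Stages: generate (or load) the cohort -> impute/log10 -> autoscale ->
robust-PCA outlier map and removal -> gender stratification -> control-class
stability ranking -> per-gender replicate-preserving 5-fold OPLS-DA with
VIP selection -> subset validation + permutation tests -> shared features
-> accurate-mass annotation.  Every stage seed derives from the master
seed; identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as anno
from . import feature_ranking as rank
from . import oplsda as op
from . import robust_outliers as ro
from . import validation as val
from .datatypes import FeatureTable, stratify_by_gender
from .preprocess import autoscale, impute_missing, log_transform
from .synthetic_data import (
    STUDY_OUTLIER_STRATA,
    CohortConfig,
    generate_cohort,
    inject_outliers,
)

log = logging.getLogger("lipidchemo")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_outliers: int = 14
    outlier_magnitude: float = 2.0
    use_study_strata: bool = True
    pca_components: int = 6
    h_fraction: float = 0.75
    removal_policy: str = "distinctive"
    ranking_B: int = 1000
    ranking_trees: int = 100
    segments: tuple = ((1, 5), (6, 10), (11, 15))
    alpha: float = 0.05
    k_folds: int = 5
    component_grid: tuple = (1, 2, 3, 4)
    subset_sizes: tuple = (10, 20, 30, 45, 60, 90, 130, 192)
    permutation_B: int = 999
    annotation_tolerance_ppm: float = 10.0
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        cohort = CohortConfig(**d.pop("cohort", {}))
        for key in ("segments", "component_grid", "subset_sizes"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(x) if isinstance(x, list) else x for x in d[key])
        return cls(cohort=cohort, **d)


def _seed_stream(master: int):
    ss = np.random.SeedSequence(master)
    while True:
        (child,) = ss.spawn(1)
        ss = child
        yield int(np.random.default_rng(child).integers(2**31 - 1))


def _gender_subset_analysis(
    table: FeatureTable, cfg: PipelineConfig, seed: int, label: str
) -> dict:
    """Per-gender disease discrimination: folds, OPLS-DA metrics, VIP."""
    y = (table.class_labels == "SCH").astype(float).to_numpy()
    logX = log_transform(impute_missing(table.intensities))
    part = op.partition_folds(table.samples, k=cfg.k_folds, seed=seed)
    rows = []
    best = None
    for i, fold in enumerate(part.folds, start=1):
        train = np.setdiff1d(np.arange(len(y)), fold)
        sub_samples = table.samples.iloc[train].reset_index()
        inner = op.partition_folds(sub_samples, k=cfg.k_folds - 1, seed=seed + i)
        cv = op.cross_validate(logX.iloc[train], y[train], inner, cfg.component_grid)
        X_tr_s, scaler = autoscale(logX.iloc[train])
        model = op.fit_oplsda(X_tr_s.to_numpy(), y[train], cv.n_components)
        model.scaling = scaler
        thr = op.decision_threshold(cv.y_cv, y[train])
        cal = op.evaluate_predictions(cv.y_cv, y[train], thr.threshold)
        X_te_s = scaler.apply(logX.iloc[fold]).to_numpy()
        pred = op.evaluate_predictions(model.predict(X_te_s), y[fold], thr.threshold)
        vip = op.vip_scores(model)
        rows.append(
            dict(fold=i, n_comp=cv.n_components, RMSECV=round(cv.rmsecv, 4),
                 RMSEP=round(pred.rmsep, 4), R2cv=round(cv.r2cv, 4),
                 R2p=round(pred.r2p, 4), vip_selected=int(vip.selected.sum()),
                 cal_accuracy=round(cal.accuracy, 4),
                 cal_misclass=round(cal.misclassification_rate, 4),
                 pred_accuracy=round(pred.accuracy, 4),
                 pred_misclass=round(pred.misclassification_rate, 4),
                 threshold=round(thr.threshold, 4))
        )
        score = (pred.accuracy, cal.accuracy, -cv.rmsecv)
        if best is None or score > best[0]:
            best = (score, i, model, vip, scaler)
    metrics = pd.DataFrame(rows)
    _, best_fold, best_model, best_vip, _ = best
    vip_table = pd.DataFrame(
        {
            "feature_id": logX.columns,
            "vip": np.round(best_vip.vip, 4),
            "lv1_loading": np.round(best_model.p_load, 4),
            "selected": best_vip.selected,
        }
    ).sort_values("vip", ascending=False)
    log.info("%s subset: %d samples, best fold %d", label, len(y), best_fold)
    return dict(metrics=metrics, vip=vip_table, best_fold=best_fold,
                vip_ranking=[str(f) for f in vip_table.feature_id], logX=logX, y=y)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the whole workflow; returns the report dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(config.seed)
    report: dict = {"config_seed": config.seed}

    # 1. cohort
    table = generate_cohort(dataclasses.replace(config.cohort, seed=next(seeds)))
    strata = STUDY_OUTLIER_STRATA if config.use_study_strata else None
    table, corrupted = inject_outliers(
        table, config.n_outliers, config.outlier_magnitude,
        seed=next(seeds), stratum_counts=strata,
    )
    table.write(out / "cohort")
    report["n_samples_initial"] = table.n_samples
    report["n_features"] = table.n_features
    report["corrupted_samples"] = sorted(corrupted)

    # 2. pre-treatment
    logX = log_transform(impute_missing(table.intensities))
    scaled, _ = autoscale(logX)

    # 3. outlier screen
    model = ro.fit_robust_pca(
        scaled.to_numpy(), k=config.pca_components,
        h_fraction=config.h_fraction, seed=next(seeds),
    )
    omap = ro.outlier_map(model, scaled.to_numpy(), sample_ids=list(scaled.index))
    omap.to_frame().to_csv(out / "outlier_map.csv")
    table_clean, removed = ro.drop_outliers(table, omap, policy=config.removal_policy)
    report["n_outliers_removed"] = len(removed)
    report["removed_samples"] = sorted(removed)
    report["n_samples_retained"] = table_clean.n_samples

    # 4. gender stratification
    male, female = stratify_by_gender(table_clean)
    report["n_male"] = male.n_samples
    report["n_female"] = female.n_samples

    # 5. control-class gender ranking (F-ratio + stability)
    control_ids = table_clean.samples.index[table_clean.class_labels == "C"]
    control = table_clean.subset_samples(control_ids)
    logC = log_transform(impute_missing(control.intensities))
    scaledC, _ = autoscale(logC)
    gender_y = control.samples["gender"].to_numpy()
    fr = rank.fisher_ratio(scaledC.to_numpy(), gender_y, alpha=config.alpha)
    stab = rank.stability_ranking(
        scaledC.to_numpy(), gender_y, control.samples,
        B=config.ranking_B, n_trees=config.ranking_trees,
        segments=config.segments, seed=next(seeds),
    )
    ranking_df = pd.DataFrame(
        {
            "feature_id": scaledC.columns,
            "f_ratio": np.round(fr.f, 4),
            "f_selected": fr.selected,
            "borda_score": stab.borda_scores,
            "mean_rank": np.round(stab.mean_rank, 2),
        }
    ).join(stab.segment_counts.set_axis(scaledC.columns))
    ranking_df.sort_values("borda_score", ascending=False).to_csv(
        out / "ranking.csv", index=False
    )
    report["f_ratio_selected"] = int(fr.selected.sum())
    report["f_ratio_df"] = [fr.df_num, fr.df_den]

    # 6. per-gender OPLS-DA
    gender_results = {}
    for label, subset in (("male", male), ("female", female)):
        res = _gender_subset_analysis(subset, config, next(seeds), label)
        res["metrics"].to_csv(out / f"model_metrics_{label}.csv", index=False)
        res["vip"].to_csv(out / f"vip_{label}.csv", index=False)
        report[f"{label}_metrics"] = res["metrics"].to_dict(orient="records")
        report[f"{label}_vip_selected"] = res["metrics"].vip_selected.tolist()
        gender_results[label] = (subset, res)

    # 7. subset validation + permutation per gender
    shared_input = {}
    for label, (subset, res) in gender_results.items():
        y = res["y"]
        sizes = [s for s in config.subset_sizes if s <= subset.n_features]
        sv = val.validate_feature_subsets(
            res["logX"], y, subset.samples.reset_index(), res["vip_ranking"],
            sizes, k=config.k_folds, component_grid=config.component_grid[:2],
            seed=next(seeds),
        )
        pd.DataFrame(
            {
                "size": sv.sizes,
                "rmsecv": [sv.rmsecv[m] for m in sv.sizes],
                "r2cv": [sv.r2cv[m] for m in sv.sizes],
                "accuracy": [sv.accuracy[m] for m in sv.sizes],
            }
        ).to_csv(out / f"subset_validation_{label}.csv", index=False)
        perm = val.permutation_test(
            res["logX"][sv.chosen_features], y, subset.samples,
            B=config.permutation_B, k=config.k_folds,
            component_grid=config.component_grid[:2], seed=next(seeds),
        )
        report[f"{label}_validated_size"] = sv.chosen_size
        report[f"{label}_permutation_p"] = perm.p_value
        report[f"{label}_permutation_observed"] = perm.observed
        shared_input[label] = sv.chosen_features
    shared = val.shared_features(shared_input["male"], shared_input["female"])
    (out / "shared_features.txt").write_text("\n".join(shared) + "\n")
    report["n_shared_features"] = len(shared)

    # 8. annotation
    annotations = anno.annotate_table(
        table.features, tolerance_ppm=config.annotation_tolerance_ppm
    )
    annotations.to_csv(out / "annotations.csv", index=False)
    report["n_annotated_features"] = int(
        annotations.dropna(subset=["adduct"]).feature_id.nunique()
    )

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(config.to_yaml())
    return report
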