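"""End-to-end run: simulate -> extract -> build dataset -> model -> report.

Every run writes its artifacts (config snapshot, manifest, feature table,
cleaned dataset, spline knots, per-model metrics, out-of-fold predictions,
ROC points, trajectory statistics) into one directory; a second run with the
same config produces byte-identical data artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import pandas as pd

from .config import PipelineConfig
from .dataset import assign_class_labels, attach_targets, clean_features, fit_infarct_spline
from .features import DEFAULT_SELECTED_16, FEATURE_NAMES, extract_feature_table, select_features
from .modeling import ClassifierSpec, CVResult, RegressorSpec, crossval_classify, crossval_regress
from .simulate import generate_cohort, generate_infarct_observations, write_cohort
from .stats import trajectory_report

logger = logging.getLogger("echoedema")

__all__ = ["run_pipeline", "resolve_feature_set", "build_dataset"]


def resolve_feature_set(name: str) -> list[str]:
    """Named feature sets: 'default16', 'all22', or 'single:<feature>'."""
    if name == "default16":
        return list(DEFAULT_SELECTED_16)
    if name == "all22":
        return list(FEATURE_NAMES)
    if name.startswith("single:"):
        feat = name.split(":", 1)[1]
        if feat not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {feat!r}")
        return [feat]
    raise ValueError(f"unknown feature set {name!r}")


def build_dataset(config: PipelineConfig, feature_table: pd.DataFrame, observations) -> pd.DataFrame:
    """Clean, label, and attach spline targets to a raw feature table."""
    cleaned = clean_features(feature_table, z_threshold=config.z_threshold)
    labeled = assign_class_labels(cleaned, boundary_h=config.boundary_h)
    spline = fit_infarct_spline(observations)
    return attach_targets(labeled, spline)


def _write_cv_result(result: CVResult, out_dir: Path, tag: str) -> None:
    agg = result.summary()
    agg.index.name = "metric"
    result.fold_metrics.to_csv(out_dir / f"{tag}_folds.csv", index=False)
    agg.to_csv(out_dir / f"{tag}_summary.csv")
    result.predictions.to_csv(out_dir / f"{tag}_predictions.csv", index=False)
    if result.roc_points is not None:
        result.roc_points.to_csv(out_dir / f"{tag}_roc.csv", index=False)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    write_waveforms: bool = False,
) -> Dict[str, CVResult]:
    """Execute the full pipeline and persist all artifacts under ``out_dir``.

    Returns the per-model cross-validation results keyed by
    ``classify_<kind>`` / ``regress_<kind>``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "config.yaml")

    logger.info(json.dumps({"stage": "simulate", "n_records": config.cohort.n_records}))
    records = generate_cohort(config.cohort)
    observations = generate_infarct_observations(config.cohort)
    write_cohort(
        records,
        observations,
        out_dir,
        boundary_h=config.boundary_h,
        write_waveforms=write_waveforms,
    )

    logger.info(json.dumps({"stage": "extract"}))
    table = extract_feature_table(records)
    table.to_csv(out_dir / "features_raw.csv", index=False)

    logger.info(json.dumps({"stage": "build_dataset"}))
    dataset = build_dataset(config, table, observations)
    dataset.to_csv(out_dir / "dataset.csv", index=False)
    spline = fit_infarct_spline(observations)
    pd.DataFrame(
        {"time_h": spline.knot_times_h, "mean_ratio": spline.knot_means}
    ).to_csv(out_dir / "spline_knots.csv", index=False)

    feature_set = resolve_feature_set(config.feature_set)
    fs16 = select_features(dataset, feature_set)

    results: Dict[str, CVResult] = {}
    for kind in config.classifiers:
        logger.info(json.dumps({"stage": "classify", "model": kind}))
        res = crossval_classify(
            fs16,
            feature_set,
            ClassifierSpec(kind=kind, seed=config.seed),
            k=config.folds,
            seed=config.seed,
            standardize_per_fold=config.fold_wise_standardization,
            group_by_subject=config.group_by_subject,
        )
        results[f"classify_{res.model_kind}"] = res
        _write_cv_result(res, out_dir, f"classify_{res.model_kind}")
    for kind in config.regressors:
        logger.info(json.dumps({"stage": "regress", "model": kind}))
        res = crossval_regress(
            fs16,
            feature_set,
            RegressorSpec(kind=kind, seed=config.seed),
            k=config.folds,
            seed=config.seed,
            standardize_per_fold=config.fold_wise_standardization,
            group_by_subject=config.group_by_subject,
        )
        results[f"regress_{res.model_kind}"] = res
        _write_cv_result(res, out_dir, f"regress_{res.model_kind}")

    logger.info(json.dumps({"stage": "report"}))
    comparisons, boxes = trajectory_report(dataset, feature_set)
    comparisons.to_csv(out_dir / "trajectory_comparisons.csv", index=False)
    boxes.to_csv(out_dir / "trajectory_box_summaries.csv", index=False)
    return results
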