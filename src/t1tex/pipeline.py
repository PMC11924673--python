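"""Pipeline orchestration: simulate -> extract -> gate -> select -> model -> longitudinal.

`run_pipeline` drives the whole analysis on a synthetic cohort, writing
every intermediate artifact (feature tables, gate report, selection record,
metric panels, GLMM fit) plus the exact configuration used into a run
directory, so reruns with the same seeds reproduce byte-identical metrics.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import (
    cross_validate,
    evaluate,
    evaluate_stump,
    fit_logistic_univariate,
    rank_models,
    stump_threshold,
)
from .features.extract import extract_case
from .glmm import fit_glmm_logistic, longitudinal_report
from .image_prep import DEFAULT_N_BINS, DEFAULT_TARGET_SPACING
from .reproducibility import gate_report, reproducibility_gate
from .selection import select_features
from .stats import PowerSpec, comparison_table, compare_groups, required_sample_size
from .synthetic import (
    SyntheticCase,
    SyntheticConfig,
    generate_longitudinal_cohort,
    generate_cohort,
    generate_reader_variants,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "gate", "select", "model", "longitudinal")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    target_spacing: float = DEFAULT_TARGET_SPACING
    n_bins: int = DEFAULT_N_BINS
    n_gate_cases: int = 15
    reader_jitter_px: float = 0.5
    gate_thresholds: tuple[float, float, float] = (0.75, 0.75, 0.10)
    train_frac: float = 0.67
    corr_threshold: float = 0.75
    cv_folds: int = 10
    n_longitudinal_patients: int = 15
    n_years: int = 3
    longitudinal_effect: float = 2.0
    seed: int = 0
    boruta_max_iter: int = 50
    boruta_trees: int = 300

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _features_for(cases: list[SyntheticCase], config: PipelineConfig) -> pd.DataFrame:
    rows = {}
    for case in cases:
        t0 = time.perf_counter()
        rows[case.case_id] = extract_case(
            case, target_spacing=config.target_spacing, n_bins=config.n_bins
        )
        logger.info("extracted %s in %.2f s", case.case_id, time.perf_counter() - t0)
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Execute the requested stages, writing artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(out / "config.json", config.as_dict())
    rng = np.random.default_rng(config.seed)
    t_start = time.perf_counter()

    # ---- simulate + extract the main cohort
    cohort = generate_cohort(config.synthetic)
    manifest = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cohort],
            "lge_status": [c.lge_status for c in cohort],
            "age": [c.age for c in cohort],
            "exam_year": [c.exam_year for c in cohort],
        }
    ).set_index("case_id")
    manifest.to_csv(out / "cohort_manifest.csv")
    if "extract" not in stages:
        return out
    features = _features_for(cohort, config)
    io.write_feature_table(out / "features.csv", features)
    labels = manifest["lge_status"]

    # ---- reproducibility gate on dedicated cases
    if "gate" in stages:
        gate_cfg = dataclasses.replace(
            config.synthetic,
            n_pos=(config.n_gate_cases + 1) // 2,
            n_neg=config.n_gate_cases // 2,
            seed=config.synthetic.seed + 104729,
        )
        gate_cases = generate_cohort(gate_cfg)
        tables: dict[tuple[int, int], pd.DataFrame] = {}
        per_case_variants = {
            case.case_id: generate_reader_variants(
                case,
                n_readers=2,
                n_repeats=2,
                jitter_px=config.reader_jitter_px,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for case in gate_cases
        }
        for k, (reader, repeat) in enumerate(
            [(1, 1), (1, 2), (2, 1), (2, 2)]
        ):
            rows = {}
            for case in gate_cases:
                variant = dataclasses.replace(
                    case, contours=per_case_variants[case.case_id][k]
                )
                rows[case.case_id] = extract_case(
                    variant, target_spacing=config.target_spacing, n_bins=config.n_bins
                )
            tables[(reader, repeat)] = pd.DataFrame.from_dict(rows, orient="index")
        decisions = reproducibility_gate(tables, config.gate_thresholds)
        report = gate_report(decisions)
        report.to_csv(out / "gate_report.csv")
        gated = [d.feature for d in decisions if d.passed]
        logger.info("gate kept %d / %d features", len(gated), len(decisions))
    else:
        gated = list(features.columns)
    io.write_json(out / "gated_features.json", {"passed": gated})
    if not gated:
        raise RuntimeError("gate stage removed every feature")

    # ---- selection cascade
    if "select" not in stages:
        return out
    selection = select_features(
        features[gated],
        labels,
        seed=config.seed,
        train_frac=config.train_frac,
        corr_threshold=config.corr_threshold,
        boruta_kwargs={
            "max_iter": config.boruta_max_iter,
            "n_estimators": config.boruta_trees,
        },
    )
    io.write_json(out / "selection.json", dataclasses.asdict(selection))
    if not selection.independent:
        raise RuntimeError("selection produced no independent features")

    # ---- group comparison of the independent features (train cohort)
    train_tbl = features.loc[selection.train_ids, selection.independent].copy()
    train_tbl["lge_status"] = labels.loc[selection.train_ids]
    comparison = comparison_table(compare_groups(train_tbl, "lge_status"))
    comparison.to_csv(out / "feature_comparison.csv")
    io.write_json(
        out / "power.json",
        {"n_per_group": required_sample_size(PowerSpec()), "cohens_d": 0.9,
         "power": 0.8, "alpha": 0.05},
    )

    # ---- per-feature logistic models
    if "model" not in stages:
        return out
    ytr = labels.loc[selection.train_ids].to_numpy()
    yte = labels.loc[selection.test_ids].to_numpy()
    fits = {}
    panel = {}
    for feat in selection.independent:
        xtr = features.loc[selection.train_ids, feat].to_numpy()
        xte = features.loc[selection.test_ids, feat].to_numpy()
        fit = fit_logistic_univariate(xtr, ytr)
        fits[feat] = fit
        cvres = cross_validate(
            xtr, ytr, folds=min(config.cv_folds, int(np.bincount(ytr).min())),
            seed=config.seed,
        )
        metrics = evaluate(fit, xte, yte)
        panel[feat] = {
            **metrics.as_dict(),
            "cv_accuracy_mean": cvres["mean"],
            "cv_accuracy_sd": cvres["sd"],
        }
    ranking = rank_models(fits)
    best = ranking[0]
    x_best_tr = features.loc[selection.train_ids, best].to_numpy()
    thr, direction = stump_threshold(x_best_tr, ytr)
    stump_metrics = evaluate_stump(
        thr, direction, features.loc[selection.test_ids, best].to_numpy(), yte
    )
    io.write_json(
        out / "model_metrics.json",
        {
            "per_feature": panel,
            "aic_ranking": ranking,
            "best_feature": best,
            "stump": stump_metrics.as_dict(),
        },
    )

    # ---- longitudinal GLMM on the best feature
    if "longitudinal" not in stages:
        return out
    lon_cases = generate_longitudinal_cohort(
        config.synthetic,
        n_patients=config.n_longitudinal_patients,
        n_years=config.n_years,
        effect_size=config.longitudinal_effect,
        seed=config.seed + 15485863,
    )
    lon_features = _features_for(lon_cases, config)
    records = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in lon_cases],
            "exam_year": [c.exam_year for c in lon_cases],
            "feature_value": lon_features[best].to_numpy(),
            "lge_status": [c.lge_status for c in lon_cases],
        }
    )
    records.to_csv(out / "longitudinal_records.csv", index=False)
    glmm = fit_glmm_logistic(records)
    io.write_json(out / "glmm.json", longitudinal_report(glmm, best))
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t_start)
    return out
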