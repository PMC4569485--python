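"""End-to-end orchestration: simulate -> express -> score -> classify -> pifta.

Each stage is a pure function of its file inputs and writes diff-able
CSV/JSON outputs; every JSON report embeds the seed, a SHA-256 hash of the
generator config and the package version, so a report bundle is fully
reproducible from its provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DEFAULT_AR_THRESHOLD,
    evaluate_threshold,
    fit_logistic,
    roc_curve,
    select_threshold,
)
from .expression import (
    build_expression_matrix,
    load_expression_matrix,
    write_expression_matrix,
)
from .panel import (
    CRM_GENES,
    PIFTA_GENES,
    Phenotype,
    Split,
    default_panel,
    load_ct_table,
    load_sample_sheet,
    validate_cohort,
)
from .progression import (
    CorrelationMethod,
    best_subset_by_adjusted_r2,
    correlate,
    longitudinal_compare,
)
from .scoring import score_cohort, write_scores
from .simulate import SyntheticCohortConfig, default_config, simulate_to_dir

__all__ = [
    "stage_simulate",
    "stage_express",
    "stage_score",
    "stage_classify",
    "stage_pifta",
    "run_all",
]

log = logging.getLogger("tcrm")
if not log.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _config_hash(config: SyntheticCohortConfig) -> str:
    payload = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: SyntheticCohortConfig) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return None if not np.isfinite(x) else x
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_report(report: dict, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(config: SyntheticCohortConfig, out_dir) -> dict:
    log.info("simulate: seed=%d -> %s", config.seed, out_dir)
    paths = simulate_to_dir(config, out_dir)
    return {str(k): str(v) for k, v in paths.items()}


def stage_express(ct_path, samples_path, out_path, log2_path=None) -> None:
    """Validate the cohort and write the ddCT fold-change matrix."""
    panel = default_panel()
    ct = load_ct_table(ct_path, panel)
    samples = load_sample_sheet(samples_path)
    cohort = validate_cohort(ct, samples, panel)
    if cohort.incomplete_samples:
        log.warning("express: incomplete samples %s", cohort.incomplete_samples)
    expr = build_expression_matrix(cohort)
    write_expression_matrix(expr, out_path)
    if log2_path is not None:
        write_expression_matrix(expr, log2_path, log2=True)
    log.info("express: %d samples x %d genes -> %s",
             len(expr.samples), len(expr.genes), out_path)


def stage_score(expr_path, out_path) -> None:
    """Score all samples with the 11-gene panel and the 7-gene subset."""
    expr = load_expression_matrix(expr_path)
    full = score_cohort(expr, CRM_GENES, "tcrm11")
    sub = score_cohort(expr, PIFTA_GENES, "pifta7")
    write_scores(pd.concat([full, sub], ignore_index=True), out_path)
    log.info("score: %d samples -> %s", len(full), out_path)


def _scores_by_split(scores: pd.DataFrame, samples: pd.DataFrame,
                     split: Split) -> tuple[np.ndarray, np.ndarray]:
    merged = samples.merge(
        scores[scores["subset_name"] == "tcrm11"], on="sample_id"
    )
    sel = merged[merged["split"] == split.value]
    labels = (sel["phenotype"] == Phenotype.AR.value).astype(int).to_numpy()
    return sel["tcrm"].to_numpy(), labels


def stage_classify(scores_path, samples_path, out_path,
                   mode: str = "derive",
                   threshold: float = DEFAULT_AR_THRESHOLD) -> dict:
    """ROC + threshold analysis of the 11-gene score for AR vs no-AR.

    ``mode="derive"`` derives the Youden-optimal cutpoint on the DISCOVERY
    split and applies it frozen to VALIDATION; ``mode="apply"`` skips the
    derivation and applies ``threshold`` (default: the published 2.24) to
    both splits.
    """
    scores = pd.read_csv(scores_path)
    samples = load_sample_sheet(samples_path)
    disc_scores, disc_labels = _scores_by_split(scores, samples,
                                                Split.DISCOVERY)
    val_scores, val_labels = _scores_by_split(scores, samples,
                                              Split.VALIDATION)
    roc = roc_curve(disc_scores, disc_labels)
    if mode == "derive":
        decision = select_threshold(roc)
        applied = decision.threshold
    elif mode == "apply":
        decision = None
        applied = float(threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # independent-correlate analysis: score + time post-transplant
    merged = samples.merge(
        scores[scores["subset_name"] == "tcrm11"], on="sample_id"
    )
    cross = merged[merged["split"] != Split.LONGITUDINAL.value]
    design = np.column_stack([
        np.ones(len(cross)),
        cross["tcrm"].to_numpy(),
        cross["timepoint_months"].to_numpy(),
    ])
    outcome = (cross["phenotype"] == Phenotype.AR.value).astype(int)
    logit = fit_logistic(design, outcome.to_numpy())

    report = {
        "note": "no multiple-testing correction applied; alpha = 0.05",
        "mode": mode,
        "roc_discovery": {
            "auc": roc.auc,
            "auc_ci": [roc.auc_ci_low, roc.auc_ci_high],
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
            "thresholds": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        },
        "threshold_decision": decision,
        "threshold_applied": applied,
        "published_threshold": DEFAULT_AR_THRESHOLD,
        "confusion_discovery": evaluate_threshold(disc_scores, disc_labels,
                                                  applied),
        "confusion_validation": evaluate_threshold(val_scores, val_labels,
                                                   applied),
        "logistic_ar_vs_score_time": {
            "predictors": ["intercept", "tcrm11", "timepoint_months"],
            "fit": {
                "coefficients": logit.coefficients,
                "standard_errors": logit.standard_errors,
                "z_values": logit.z_values,
                "p_values": logit.p_values,
                "converged": logit.converged,
                "separation": logit.separation,
                "n_iterations": logit.n_iterations,
            },
        },
    }
    _write_report(report, out_path)
    log.info("classify: AUC=%.3f threshold=%.3f -> %s",
             roc.auc, applied, out_path)
    return report


def stage_pifta(expr_path, samples_path, scores_path, out_path) -> dict:
    """Banff-lesion correlation and progressive-IFTA analyses."""
    expr = load_expression_matrix(expr_path)
    samples = load_sample_sheet(samples_path)
    scores = pd.read_csv(scores_path)
    full = scores[scores["subset_name"] == "tcrm11"]
    merged = samples.merge(full, on="sample_id")

    # lesion correlation over samples carrying Banff grades
    banff = {}
    for col in ("banff_t", "banff_i"):
        sel = merged[merged[col].notna()]
        if len(sel) >= 3:
            banff[col] = {
                "pearson": correlate(sel["tcrm"], sel[col].astype(float),
                                     CorrelationMethod.PEARSON),
                "spearman": correlate(sel["tcrm"], sel[col].astype(float),
                                      CorrelationMethod.SPEARMAN),
            }

    # exhaustive adjusted-R2 subset search on 6-month protocol biopsies
    six = merged[
        (merged["split"] == Split.LONGITUDINAL.value)
        & (merged["timepoint_months"] == 6.0)
    ].sort_values("sample_id")
    x = expr.log2_fc.loc[six["sample_id"], list(CRM_GENES)]
    y = (six["phenotype"] == Phenotype.PIFTA_P.value).astype(int).to_numpy()
    selection = best_subset_by_adjusted_r2(x, y)
    top = selection.search_log.nlargest(20, "adjusted_r2")

    longitudinal = longitudinal_compare(full, samples)

    report = {
        "note": "no multiple-testing correction applied; alpha = 0.05",
        "banff_correlation": banff,
        "subset_selection": {
            "best_subset": list(selection.best_subset),
            "best_adjusted_r2": selection.best_adjusted_r2,
            "n_subsets_evaluated": int(len(selection.search_log)),
            "single_gene_adjusted_r2": selection.per_gene_single_r2,
            "top20": [
                {"subset": list(r.subset), "adjusted_r2": r.adjusted_r2}
                for r in top.itertuples(index=False)
            ],
        },
        "longitudinal": longitudinal,
    }
    _write_report(report, out_path)
    log.info("pifta: best subset %s (adjR2=%.3f) -> %s",
             selection.best_subset, selection.best_adjusted_r2, out_path)
    return report


def run_all(config: SyntheticCohortConfig | None = None, out_dir=".") -> dict:
    """Run the five stages end to end on a simulated cohort."""
    config = config or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    stages: dict[str, str] = {}
    try:
        paths = stage_simulate(config, out / "data")
        stages["simulate"] = "ok"
        expr_path = out / "expression_matrix.csv"
        stage_express(paths["ct_table"], paths["samples"], expr_path,
                      out / "expression_log2.csv")
        stages["express"] = "ok"
        scores_path = out / "scores.csv"
        stage_score(expr_path, scores_path)
        stages["score"] = "ok"
        classify_report = stage_classify(scores_path, paths["samples"],
                                         out / "classify_report.json")
        stages["classify"] = "ok"
        pifta_report = stage_pifta(expr_path, paths["samples"], scores_path,
                                   out / "pifta_report.json")
        stages["pifta"] = "ok"
    except Exception as exc:
        failed = {"simulate", "express", "score", "classify",
                  "pifta"} - set(stages)
        raise RuntimeError(
            f"pipeline failed in stage(s) {sorted(failed)}: {exc}"
        ) from exc
    bundle = {
        "provenance": prov,
        "stages": stages,
        "classify": classify_report,
        "pifta": pifta_report,
    }
    for name in ("classify_report.json", "pifta_report.json"):
        path = out / name
        data = json.loads(path.read_text())
        data["provenance"] = prov
        _write_report(data, path)
    _write_report(bundle, out / "report_bundle.json")
    return _jsonable(bundle)
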