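"""End-to-end discovery -> stability -> validation workflow.

Stage order: QC -> normalization selection -> differential expression ->
LASSO signature (10-fold CV, one-SE rule) -> bootstrap stability -> LOOCV /
ROC evaluation -> validation cohort -> random-signature null.  Every stage
writes its artifact under the output directory and appends a record (seed,
outputs, warnings, wall time) to a machine-readable manifest.  One global
seed deterministically derives per-stage seeds, so stages can be rerun in
isolation.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diffexp, evaluate, normalize, preprocess, signature as sig
from .data import MirsigError
from .simulate import SimulationConfig, simulate_cohort, simulate_validation_cohort

log = logging.getLogger("mirsig")


@dataclass
class PipelineConfig:
    """Configuration of a full run (paths or simulation parameters)."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # cohorts: either file paths {"ct": ..., "samples": ...} or {"simulate": {...}}
    discovery: dict = field(default_factory=lambda: {"simulate": {}})
    validation: dict | None = None
    undetermined_ct: float = 40.0
    ct_max: float = 33.0
    informative_policy: str = "all"
    normalization: str = "auto"
    fc_min: float = 2.0
    alpha: float = 0.05
    cv_folds: int = 10
    n_lambda: int = 100
    bootstrap_b: int = 10_000
    bootstrap_n_lambda: int = 30
    bootstrap_cv_folds: int = 5
    null_m: int = 1000
    pr_bootstrap: int = 2000
    recalibrate_validation_threshold: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise MirsigError("alpha must be in (0, 1)")
        if self.fc_min < 1:
            raise MirsigError("fc_min must be >= 1")
        if self.cv_folds < 2:
            raise MirsigError("cv_folds must be >= 2")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _load_cohort(source: dict, global_seed: int, which: str):
    if "simulate" in source:
        params = dict(source["simulate"])
        params.setdefault("seed", stage_seed(global_seed, f"simulate:{which}"))
        cfg = SimulationConfig(**params)
        if which == "validation":
            base = SimulationConfig(
                **{**params, "seed": stage_seed(global_seed, "simulate:discovery")}
            )
            disc = simulate_cohort(base)
            cohort = simulate_validation_cohort(
                base,
                disc.truth,
                n_patients=cfg.n_patients,
                n_controls=cfg.n_controls,
                seed=cfg.seed,
            )
        else:
            cohort = simulate_cohort(cfg)
        return cohort.ct_matrix, cohort.sample_sheet
    m = preprocess.read_ct_matrix(source["ct"])
    sheet = preprocess.read_sample_sheet(source["samples"])
    return m, sheet


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.record = {
            "config": asdict(config),
            "seed": config.seed,
            "stages": [],
            "summary": {},
        }

    def add(self, stage, seed, outputs, warnings_seen, wall_time, **extra):
        self.record["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "outputs": outputs,
                "warnings": warnings_seen,
                "wall_time_s": round(wall_time, 4),
                **extra,
            }
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.record, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _prep_cohort(m, sheet, config, out, tag, manifest):
    """QC, imputation and informativeness filtering for one cohort."""
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as seen:
        warnings.simplefilter("always")
        qc = preprocess.hemolysis_qc(m)
        m2, sheet2 = preprocess.apply_sample_qc(m, sheet, qc)
        n_undet = m2.n_undetermined
        m3 = preprocess.impute_undetermined(m2, config.undetermined_ct)
        m4, filt = preprocess.filter_informative(
            m3, ct_max=config.ct_max, policy=config.informative_policy, sheet=sheet2
        )
    qc.n_imputed = n_undet
    qc.notes.extend(filt.notes)
    qc.assays_kept = filt.assays_kept
    qc.assays_dropped = filt.assays_dropped
    qc_path = out / f"qc_{tag}.json"
    qc.to_json(qc_path)
    manifest.add(
        f"qc:{tag}",
        None,
        [str(qc_path)],
        [str(w.message) for w in seen],
        time.perf_counter() - t0,
        n_samples_kept=len(m4.sample_ids),
        n_assays_kept=len(m4.assay_names),
        n_imputed=n_undet,
    )
    return m4, sheet2


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)

    def _stage(name):
        log.info("stage %s", name)
        return time.perf_counter(), stage_seed(config.seed, name)

    try:
        # --- load / simulate cohorts -----------------------------------
        t0, _ = _stage("load")
        m_disc, sheet_disc = _load_cohort(config.discovery, config.seed, "discovery")
        manifest.add(
            "load:discovery",
            stage_seed(config.seed, "simulate:discovery"),
            [],
            [],
            time.perf_counter() - t0,
            n_samples=len(m_disc.sample_ids),
            n_assays=len(m_disc.assay_names),
        )

        # --- QC ----------------------------------------------------------
        m_disc, sheet_disc = _prep_cohort(
            m_disc, sheet_disc, config, out, "discovery", manifest
        )

        # --- normalization ------------------------------------------------
        t0, _ = _stage("normalize")
        with warnings.catch_warnings(record=True) as seen:
            warnings.simplefilter("always")
            if config.normalization == "auto":
                nm, scores = normalize.select_normalization(m_disc)
            else:
                nm, scores = normalize.select_normalization(
                    m_disc, methods=[config.normalization]
                )
        norm_path = out / "normalized_discovery.tsv"
        nm.to_tsv(norm_path)
        scores_path = out / "normalization_scores.json"
        scores_path.write_text(
            json.dumps(
                {
                    "selected": nm.method,
                    "scores": [asdict(s) for s in scores],
                },
                indent=2,
            )
        )
        manifest.add(
            "normalize",
            None,
            [str(norm_path), str(scores_path)],
            [str(w.message) for w in seen],
            time.perf_counter() - t0,
            method=nm.method,
        )

        # --- differential expression --------------------------------------
        t0, _ = _stage("diffexp")
        de = diffexp.differential_expression(
            nm, sheet_disc, fc_min=config.fc_min, alpha=config.alpha
        )
        de_assays = diffexp.differentially_expressed_assays(de)
        de_path = out / "diffexp_discovery.csv"
        de.to_csv(de_path)
        manifest.add(
            "diffexp", None, [str(de_path)], [], time.perf_counter() - t0,
            n_differential=len(de_assays),
        )
        if not de_assays:
            raise MirsigError(
                "no differentially expressed assays; cannot build a signature"
            )

        # --- LASSO signature ----------------------------------------------
        t0, seed_fit = _stage("fit_signature")
        X = nm.values.loc[de_assays].T  # samples x candidate assays
        y = sheet_disc.labels(X.index)
        with warnings.catch_warnings(record=True) as seen:
            warnings.simplefilter("always")
            path = sig.fit_lasso_path(X, y, n_lambda=config.n_lambda)
            cv = sig.select_lambda_1se(path, k=config.cv_folds, seed=seed_fit)
            model = sig.extract_signature(path, cv.lambda_1se, cv)
        model.meta["cv_seed"] = seed_fit
        sig_path = out / "signature.json"
        manifest.add(
            "fit_signature",
            seed_fit,
            [str(sig_path)],
            [str(w.message) for w in seen],
            time.perf_counter() - t0,
            signature=model.assays,
            lambda_min=cv.lambda_min,
            lambda_1se=cv.lambda_1se,
        )
        if not model.assays:
            raise MirsigError("empty signature at lambda_1se; nothing to evaluate")

        # --- bootstrap stability -------------------------------------------
        if config.bootstrap_b > 0:
            t0, seed_boot = _stage("stability")
            stab = sig.bootstrap_stability(
                X,
                y,
                model.assays,
                B=config.bootstrap_b,
                seed=seed_boot,
                n_lambda=config.bootstrap_n_lambda,
                k=config.bootstrap_cv_folds,
            )
            stab_path = out / "stability.json"
            stab.to_json(stab_path)
            manifest.add(
                "stability", seed_boot, [str(stab_path)], [],
                time.perf_counter() - t0,
                overlap_frequency=stab.overlap_frequency,
                p_value=stab.p_value,
            )
            manifest.record["summary"]["stability_p"] = stab.p_value
        else:
            manifest.add("stability", None, [], [], 0.0, skipped=True)

        # --- LOOCV evaluation on discovery ---------------------------------
        t0, seed_eval = _stage("evaluate:discovery")
        report = evaluate.evaluate_loocv(
            X, y, model.assays, n_boot=config.pr_bootstrap, seed=seed_eval
        )
        model.threshold = report.threshold
        model.to_json(sig_path)
        eval_path = out / "eval_discovery.json"
        report.to_json(eval_path)
        report.write_curves(out / "roc_discovery.csv", out / "pr_discovery.csv")
        manifest.add(
            "evaluate:discovery", seed_eval, [str(eval_path)], [],
            time.perf_counter() - t0,
            auc_roc=report.roc.auc, auc_pr=report.pr.auc,
            metrics=report.metrics,
        )
        manifest.record["summary"]["discovery"] = {
            "signature": model.assays,
            "auc_roc": report.roc.auc,
            "auc_roc_ci": list(report.roc.ci),
            "auc_pr": report.pr.auc,
            "auc_pr_ci": list(report.pr.ci),
            **{k: report.metrics[k] for k in (
                "accuracy", "sensitivity", "specificity",
                "positive_prediction_rate", "negative_prediction_rate")},
        }

        # --- validation cohort ----------------------------------------------
        if config.validation is None:
            manifest.add("validate", None, [], [], 0.0, skipped=True)
            manifest.add("random_null", None, [], [], 0.0, skipped=True)
            manifest.record["summary"]["validation"] = "skipped"
        else:
            t0, seed_val = _stage("validate")
            m_val, sheet_val = _load_cohort(
                config.validation, config.seed, "validation"
            )
            m_val, sheet_val = _prep_cohort(
                m_val, sheet_val, config, out, "validation", manifest
            )
            m_val_n = _normalize_like(m_val, nm.method)
            X_val = m_val_n.values.reindex(model.assays).T
            if X_val.isna().to_numpy().any():
                raise MirsigError(
                    "signature assays missing/censored in validation cohort"
                )
            y_val = sheet_val.labels(X_val.index)
            # the final model applied to new cohorts is the unpenalized refit
            # of the signature on the full discovery cohort
            final_model = sig.refit_signature(X, y, model.assays)
            final_model.threshold = model.threshold
            val_report = evaluate.evaluate_on_cohort(
                final_model,
                X_val,
                y_val,
                recalibrate_threshold=config.recalibrate_validation_threshold,
                n_boot=config.pr_bootstrap,
                seed=seed_val,
            )
            val_path = out / "eval_validation.json"
            val_report.to_json(val_path)
            val_report.write_curves(
                out / "roc_validation.csv", out / "pr_validation.csv"
            )
            manifest.add(
                "validate", seed_val, [str(val_path)], [],
                time.perf_counter() - t0,
                auc_roc=val_report.roc.auc, auc_pr=val_report.pr.auc,
                metrics=val_report.metrics,
            )
            manifest.record["summary"]["validation"] = {
                "auc_roc": val_report.roc.auc,
                "auc_roc_ci": list(val_report.roc.ci),
                "auc_pr": val_report.pr.auc,
                "auc_pr_ci": list(val_report.pr.ci),
                **{k: val_report.metrics[k] for k in (
                    "accuracy", "sensitivity", "specificity",
                    "positive_prediction_rate", "negative_prediction_rate")},
            }

            # --- random-signature null -----------------------------------
            if config.null_m > 0:
                t0, seed_null = _stage("random_null")
                pool = [a for a in m_val_n.assay_names if a in nm.values.index]
                X_tr_pool = nm.values.loc[pool].T
                X_te_pool = m_val_n.values.loc[pool].T
                null = sig.random_signature_null(
                    X_tr_pool,
                    y,
                    X_te_pool,
                    y_val,
                    size=len(model.assays),
                    observed_accuracy=val_report.metrics["accuracy"],
                    M=config.null_m,
                    seed=seed_null,
                )
                null_path = out / "random_null.json"
                null.to_json(null_path)
                manifest.add(
                    "random_null", seed_null, [str(null_path)], [],
                    time.perf_counter() - t0, p_value=null.p_value,
                )
                manifest.record["summary"]["null_p"] = null.p_value
            else:
                manifest.add("random_null", None, [], [], 0.0, skipped=True)
    except Exception as exc:  # noqa: BLE001 - converted to a machine-readable record
        manifest.record["error"] = {
            "stage": manifest.record["stages"][-1]["stage"]
            if manifest.record["stages"]
            else "init",
            "type": type(exc).__name__,
            "message": str(exc),
        }
        manifest.write(out / "manifest.json")
        raise

    manifest.write(out / "manifest.json")
    report_txt = make_report(manifest.record)
    (out / "report.txt").write_text(report_txt)
    return manifest.record


def _normalize_like(m, method: str):
    """Normalize a new cohort with the method selected on discovery."""
    nm, _ = normalize.select_normalization(m, methods=[method])
    return nm


_REPORT_KEYS = (
    ("accuracy", "Accuracy"),
    ("sensitivity", "Sensitivity"),
    ("specificity", "Specificity"),
    ("positive_prediction_rate", "Positive Prediction Rate"),
    ("negative_prediction_rate", "Negative Prediction Rate"),
)


def _fmt(v):
    if v is None:
        return "undefined"
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)


def make_report(manifest: dict) -> str:
    """Human-readable performance summary built purely from the manifest."""
    s = manifest.get("summary", {})
    lines = ["Signature performance report", "=" * 29, ""]
    disc = s.get("discovery")
    if disc:
        lines.append(f"Signature: {', '.join(disc['signature'])}")
        lines.append("")
    for name, block in (("Discovery cohort", disc),
                        ("Validation cohort", s.get("validation"))):
        lines.append(name)
        lines.append("-" * len(name))
        if block is None or block == "skipped" or not isinstance(block, dict):
            lines.append("  not run")
            lines.append("")
            continue
        for key, label in _REPORT_KEYS:
            lines.append(f"  {label:28s} {_fmt(block.get(key))}")
        lo, hi = block["auc_roc_ci"]
        lines.append(
            f"  {'AUC ROC (95% CI)':28s} {block['auc_roc']:.2f} ({lo:.2f}, {hi:.2f})"
        )
        lo, hi = block["auc_pr_ci"]
        lines.append(
            f"  {'AUC PR (95% CI)':28s} {block['auc_pr']:.2f} ({lo:.2f}, {hi:.2f})"
        )
        lines.append("")
    lines.append(
        f"Bootstrap stability p: "
        f"{_fmt(s['stability_p']) if 'stability_p' in s else 'not run'}"
    )
    lines.append(
        f"Random-signature null p: "
        f"{_fmt(s['null_p']) if 'null_p' in s else 'not run'}"
    )
    return "\n".join(lines) + "\n"
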