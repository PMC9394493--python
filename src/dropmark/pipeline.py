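"""Deterministic orchestration: simulate -> preprocess -> stack -> fit -> evaluate.

``run_pipeline`` executes every stage in order, writing versioned CSV/JSON
artifacts plus a manifest (config, seed, per-stage row and event counts,
coefficient table, AUC table).  The same config and seed reproduce every
artifact byte-identically; any stage failure aborts with the stage name
and a reproduction command.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, save_config, load_config, _config_to_dict
from .cox import fit_supermodel
from .evaluate import (
    auc_curve,
    compare_baseline_only,
    cross_validate,
    dynamic_roc,
    landmark_lp_table,
    summarize_dropout_reasons,
)
from .landmarking import landmark_grid, last_landmark_at_risk, stack_landmarks
from .preprocess import preprocess
from .simulate import SimulatedCohort, simulate_cohort

__all__ = ["run_pipeline", "load_cohort"]


class StageError(RuntimeError):
    def __init__(self, stage: str, out_dir, err: Exception):
        super().__init__(
            f"pipeline stage '{stage}' failed: {err}\n"
            f"reproduce with: dropmark run --config {Path(out_dir) / 'config.yaml'} "
            f"--out {out_dir}"
        )
        self.stage = stage


def load_cohort(data_dir) -> SimulatedCohort:
    """Reload a simulated cohort written by ``SimulatedCohort.to_csv``/CLI."""
    d = Path(data_dir)
    cfg = load_config(d / "config.yaml")
    truth_path = d / "truth.csv"
    return SimulatedCohort(
        baseline=pd.read_csv(d / "baseline.csv"),
        weekly=pd.read_csv(d / "weekly_status.csv"),
        outcomes=pd.read_csv(d / "outcomes.csv"),
        truth=pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame(),
        config=cfg.generator,
    )


def _stacked_row_conservation(clean) -> int:
    """Sum over recruits of (last landmark at risk - entry week + 1)."""
    out = clean.outcomes.set_index("recruit_id")
    entry = clean.entry.set_index("recruit_id")["entry_week"]
    last = last_landmark_at_risk(out["day"].to_numpy(), clean.duration_weeks - 1)
    n_rows = np.maximum(last - entry.reindex(out.index).to_numpy() + 1, 0)
    return int(n_rows.sum())


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis and return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    gen_cfg = config.generator.replace(seed=config.seed)
    manifest: dict = {
        "config": _config_to_dict(config),
        "seed": config.seed,
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    try:
        if gen_cfg.n_recruits == 0:
            raise ValueError("n_recruits is 0: nothing to simulate")
        cohort = simulate_cohort(gen_cfg, degrade=config.apply_missingness)
        cohort.to_csv(out)
    except Exception as err:  # noqa: BLE001
        raise StageError("simulate", out, err) from err
    manifest["stages"]["simulate"] = {
        "n_recruits": int(len(cohort.baseline)),
        "n_dropouts": int(cohort.outcomes["event"].sum()),
        "dropout_pct": round(100 * float(cohort.outcomes["event"].mean()), 3),
    }

    # --- preprocess ---------------------------------------------------
    try:
        clean = preprocess(
            cohort,
            max_missing_frac=config.max_missing_frac,
            min_variance=config.min_variance,
            pain_carry=config.pain_carry,
        )
        clean.weekly.to_csv(out / "weekly_clean.csv", index=False)
        clean.screen_report.to_csv(out / "screening.csv", index=False)
    except Exception as err:  # noqa: BLE001
        raise StageError("preprocess", out, err) from err
    manifest["stages"]["preprocess"] = {
        "n_retained": int(len(clean.baseline)),
        "n_excluded": int(len(clean.exclusions)),
        "n_imputed_cells": int(len(clean.imputation_log)),
        "items_kept": clean.items,
    }

    # --- landmarking ---------------------------------------------------
    try:
        grid = landmark_grid(clean.duration_weeks)
        stacked = stack_landmarks(clean, grid)
        stacked.to_csv(out / "stacked.csv", index=False)
    except Exception as err:  # noqa: BLE001
        raise StageError("landmark", out, err) from err
    n_events = int(stacked["event"].sum())
    manifest["stages"]["landmark"] = {
        "n_landmarks": int(len(grid)),
        "n_rows": int(len(stacked)),
        "n_rows_expected": _stacked_row_conservation(clean),
        "n_events": n_events,
        "events_per_predictor": round(n_events / 21, 2),
    }

    # --- fit ----------------------------------------------------------
    try:
        model = fit_supermodel(
            clean,
            coding=config.landmark_coding,
            ties=config.ties_method,
            variance=config.variance_method,
            stacked=stacked,
        )
        coef = model.summary().round(6)
        coef.rename_axis("predictor").to_csv(out / "coefficients.csv")
    except Exception as err:  # noqa: BLE001
        raise StageError("fit", out, err) from err
    manifest["stages"]["fit"] = {
        "loglik": round(model.fit.loglik, 6),
        "n_iter": model.fit.n_iter,
        "coefficients": {k: round(float(v), 6) for k, v in model.fit.params.items()},
    }

    # --- evaluate -------------------------------------------------------
    try:
        eval_days = [7 * w for w in config.eval_weeks]
        comparison, _, _ = compare_baseline_only(
            clean, eval_days, config.roc_window_days,
            coding=config.landmark_coding, ties=config.ties_method,
        )
        lp_table = landmark_lp_table(model, stacked)
        full_curve = auc_curve(
            lp_table, clean.outcomes, grid["day"], config.roc_window_days, len(grid)
        )
        full_curve.round(6).to_csv(out / "auc.csv")
        roc_rows = []
        thr = {}
        for t in eval_days:
            roc = dynamic_roc(lp_table, clean.outcomes, t, config.roc_window_days, len(grid))
            if roc is None:
                continue
            pts = roc.curve.copy()
            pts.insert(0, "day", t)
            roc_rows.append(pts)
            thr[str(t)] = {
                "threshold": round(roc.optimal_threshold, 6),
                "sensitivity": round(roc.sensitivity, 6),
                "specificity": round(roc.specificity, 6),
            }
        if roc_rows:
            pd.concat(roc_rows, ignore_index=True).round(6).to_csv(out / "roc_points.csv", index=False)
        comparison.round(6).to_csv(out / "auc_comparison.csv", index=False)
        reasons = summarize_dropout_reasons(cohort.outcomes)
    except Exception as err:  # noqa: BLE001
        raise StageError("evaluate", out, err) from err
    manifest["stages"]["evaluate"] = {
        "auc": {str(int(r["day"])): {
            "supermodel": round(float(r["auc_supermodel"]), 6),
            "baseline_only": round(float(r["auc_baseline"]), 6),
        } for _, r in comparison.iterrows()},
        "thresholds": thr,
        "dropout_reasons": reasons,
    }

    # --- cross-validate -------------------------------------------------
    if config.cv_repeats > 0:
        try:
            cv = cross_validate(
                clean, k=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
                eval_days=eval_days, window_days=config.roc_window_days,
                coding=config.landmark_coding, ties=config.ties_method,
            )
            cv.summary().round(6).rename_axis("day").to_csv(out / "cv_auc.csv")
        except Exception as err:  # noqa: BLE001
            raise StageError("crossval", out, err) from err
        manifest["stages"]["crossval"] = {
            "k": config.cv_folds,
            "repeats": config.cv_repeats,
            "cv_auc_mean": {str(d): round(float(v), 6) for d, v in cv.cv_auc.mean(axis=0).items()},
            "n_resampled": cv.n_resampled,
        }

    body = json.dumps(manifest, sort_keys=True, indent=1, default=float)
    manifest["manifest_sha256"] = hashlib.sha256(body.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")
    return manifest
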