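"""Time-dependent discrimination and validation of the landmark supermodel.

The incident/dynamic AUC at day t is the probability that a recruit who
drops out around t has a higher model score (linear predictor) than a
recruit who stays in training beyond t.  Cases are dropouts with an event
day inside a +/- ``window_days`` smoothing window around t (scored at
their last at-risk landmark); controls are recruits still in training
after the window (scored at the last landmark at or before t); ties count
one half.  Operating thresholds maximize Youden's J.  Model validation is
repeated k-fold cross-validation with folds splitting recruits, never
rows, so no recruit's landmarks leak between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rng import stream
from .design import build_design, baseline_design
from .landmarking import landmark_grid, last_landmark_at_risk, stack_landmarks
from .cox import CoxFit, SupermodelFit, fit_cox, fit_supermodel
from .preprocess import CleanCohort

__all__ = [
    "DynamicROC",
    "CVResult",
    "landmark_lp_table",
    "dynamic_auc",
    "dynamic_roc",
    "auc_curve",
    "cross_validate",
    "compare_baseline_only",
    "summarize_dropout_reasons",
]


def landmark_lp_table(model: SupermodelFit, stacked: pd.DataFrame) -> pd.DataFrame:
    """Per recruit-landmark linear predictors: columns recruit_id, s, lp."""
    out = stacked[["recruit_id", "s"]].copy()
    out["lp"] = model.linear_predictors(stacked).to_numpy()
    return out


def _case_control_lps(
    lp_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    t: float,
    window_days: int,
    n_landmarks: int,
) -> tuple[np.ndarray, np.ndarray]:
    out = outcomes
    lps = lp_table.set_index(["recruit_id", "s"])["lp"]

    is_case = (out["event"] == 1) & (out["day"] >= t - window_days) & (out["day"] <= t + window_days)
    case_ids = out.loc[is_case, "recruit_id"].to_numpy()
    case_s = last_landmark_at_risk(out.loc[is_case, "day"].to_numpy(), n_landmarks)
    ok = case_s >= 1
    case_lp = lps.reindex(
        pd.MultiIndex.from_arrays([case_ids[ok], case_s[ok]])
    ).to_numpy()

    is_ctrl = out["day"] > t + window_days
    ctrl_ids = out.loc[is_ctrl, "recruit_id"].to_numpy()
    s_ctrl = max(int(t // 7), 1)
    ctrl_lp = lps.reindex(
        pd.MultiIndex.from_arrays([ctrl_ids, np.full(len(ctrl_ids), s_ctrl)])
    ).to_numpy()

    return case_lp[~np.isnan(case_lp)], ctrl_lp[~np.isnan(ctrl_lp)]


def _pairwise_auc(case_lp: np.ndarray, ctrl_lp: np.ndarray) -> float:
    """Midrank (tie = 1/2) pairwise AUC; NaN when either set is empty."""
    n1, n0 = len(case_lp), len(ctrl_lp)
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([case_lp, ctrl_lp]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def dynamic_auc(
    lp_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    t: float,
    window_days: int = 7,
    n_landmarks: int | None = None,
) -> float:
    """Incident/dynamic AUC(t); NaN when no scorable cases or controls."""
    if n_landmarks is None:
        n_landmarks = int(lp_table["s"].max())
    case_lp, ctrl_lp = _case_control_lps(lp_table, outcomes, t, window_days, n_landmarks)
    return _pairwise_auc(case_lp, ctrl_lp)


@dataclass
class DynamicROC:
    """Dynamic ROC at one evaluation day with its Youden-optimal threshold."""

    t: float
    window_days: int
    curve: pd.DataFrame  # threshold, sensitivity, specificity
    auc: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int


def dynamic_roc(
    lp_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    t: float,
    window_days: int = 7,
    n_landmarks: int | None = None,
) -> DynamicROC | None:
    """Dynamic ROC curve at day ``t``.

    The smoothed variant (``window_days > 0``) pools cases over the window;
    ``window_days = 0`` gives the unsmoothed single-day curve.  The curve is
    swept over all distinct LP thresholds (classification: positive when
    LP >= threshold); the optimal threshold maximizes sensitivity +
    specificity - 1, ties broken toward higher specificity.  Returns None
    when either the case or control set is empty.
    """
    if n_landmarks is None:
        n_landmarks = int(lp_table["s"].max())
    case_lp, ctrl_lp = _case_control_lps(lp_table, outcomes, t, window_days, n_landmarks)
    n1, n0 = len(case_lp), len(ctrl_lp)
    if n1 == 0 or n0 == 0:
        return None

    thresholds = np.unique(np.concatenate([case_lp, ctrl_lp]))[::-1]
    sens = np.array([(case_lp >= c).mean() for c in thresholds])
    spec = np.array([(ctrl_lp < c).mean() for c in thresholds])
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], thresholds]),
            "sensitivity": np.concatenate([[0.0], sens]),
            "specificity": np.concatenate([[1.0], spec]),
        }
    )
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    # thresholds are sorted descending, so the first maximizer has the
    # highest threshold, hence the highest specificity
    pick = best[0]
    return DynamicROC(
        t=float(t),
        window_days=window_days,
        curve=curve,
        auc=_pairwise_auc(case_lp, ctrl_lp),
        optimal_threshold=float(thresholds[pick]),
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        n_cases=n1,
        n_controls=n0,
    )


def auc_curve(
    lp_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    days,
    window_days: int = 7,
    n_landmarks: int | None = None,
) -> pd.Series:
    """AUC(t) over a grid of evaluation days."""
    vals = {
        int(t): dynamic_auc(lp_table, outcomes, t, window_days, n_landmarks) for t in days
    }
    return pd.Series(vals, name="auc").rename_axis("day")


@dataclass
class CVResult:
    """Repeated k-fold cross-validation output."""

    folds: pd.DataFrame  # repeat, recruit_id, fold
    oof_lp: list[pd.DataFrame]  # per repeat: recruit_id, s, lp (out of fold)
    cv_auc: pd.DataFrame  # repeat x day AUC(t)
    apparent_auc: pd.Series
    n_resampled: int

    def summary(self) -> pd.DataFrame:
        """Mean and 2.5/97.5 percentile bands of the cross-validated AUC(t)."""
        return pd.DataFrame(
            {
                "apparent": self.apparent_auc,
                "cv_mean": self.cv_auc.mean(axis=0),
                "cv_lo": self.cv_auc.quantile(0.025, axis=0),
                "cv_hi": self.cv_auc.quantile(0.975, axis=0),
            }
        )


def _stratified_folds(ids, strata, k, rng) -> pd.Series:
    fold = pd.Series(-1, index=ids)
    for val in np.unique(strata):
        members = np.asarray(ids)[np.asarray(strata) == val]
        perm = rng.permutation(members)
        fold.loc[perm] = np.arange(len(perm)) % k
    return fold


def cross_validate(
    clean: CleanCohort,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
    eval_days=None,
    window_days: int = 7,
    coding: str = "s_minus_1",
    ties: str = "breslow",
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the supermodel.

    Folds partition recruits (stratified by dropout status); per repeat the
    supermodel is refitted on k-1 folds and held-out recruits are scored by
    a model never trained on them.  A training split without events is
    flagged and the repeat's folds are redrawn.  Deterministic given
    ``seed``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = stream(seed, "cv")
    stacked = stack_landmarks(clean)
    design = build_design(stacked, coding=coding)
    grid = landmark_grid(clean.duration_weeks)
    if eval_days is None:
        eval_days = grid["day"].to_list()
    n_landmarks = int(grid["s"].max())

    ids = clean.outcomes["recruit_id"].to_numpy()
    strata = clean.outcomes["event"].to_numpy()
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} recruits into {k} folds")

    apparent_model = fit_supermodel(clean, coding=coding, ties=ties, stacked=stacked)
    apparent = auc_curve(
        landmark_lp_table(apparent_model, stacked), clean.outcomes, eval_days,
        window_days, n_landmarks,
    )

    fold_rows = []
    oof_tables = []
    curves = []
    n_resampled = 0
    row_ids = stacked["recruit_id"].to_numpy()
    for rep in range(repeats):
        for _attempt in range(20):
            fold = _stratified_folds(ids, strata, k, rng)
            ok = all(
                clean.outcomes.loc[~clean.outcomes["recruit_id"].isin(fold.index[fold == f]), "event"].sum() > 0
                for f in range(k)
            )
            if ok:
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not draw folds with events in every training split")

        lp = np.full(len(stacked), np.nan)
        row_fold = fold.reindex(row_ids).to_numpy()
        for f in range(k):
            test = row_fold == f
            train = ~test
            fit = fit_cox(
                design[train],
                stacked.loc[train, "start"],
                stacked.loc[train, "stop"],
                stacked.loc[train, "event"],
                ties=ties,
            )
            lp[test] = design[test].to_numpy() @ fit.params.to_numpy()
        oof = stacked[["recruit_id", "s"]].copy()
        oof["lp"] = lp
        oof_tables.append(oof)
        curves.append(
            auc_curve(oof, clean.outcomes, eval_days, window_days, n_landmarks).rename(rep)
        )
        fr = fold.rename("fold").rename_axis("recruit_id").reset_index()
        fr.insert(0, "repeat", rep)
        fold_rows.append(fr)

    cv_auc = pd.DataFrame(curves)
    cv_auc.index.name = "repeat"
    return CVResult(
        folds=pd.concat(fold_rows, ignore_index=True),
        oof_lp=oof_tables,
        cv_auc=cv_auc,
        apparent_auc=apparent,
        n_resampled=n_resampled,
    )


def compare_baseline_only(
    clean: CleanCohort,
    eval_days=(7, 28, 84),
    window_days: int = 7,
    coding: str = "s_minus_1",
    ties: str = "breslow",
) -> tuple[pd.DataFrame, SupermodelFit, CoxFit]:
    """AUC(t) of the landmark supermodel vs a baseline-only Cox model.

    The comparison model is a conventional proportional-hazards fit on the
    9 baseline covariates with time-to-dropout from day 0 — no landmarking
    and no weekly information, so its linear predictor is constant over
    landmarks.  Both models are evaluated with the same case/control sets.
    """
    stacked = stack_landmarks(clean)
    supermodel = fit_supermodel(clean, coding=coding, ties=ties, stacked=stacked)
    lp_super = landmark_lp_table(supermodel, stacked)

    xb = baseline_design(clean.baseline)
    base_fit = fit_cox(
        xb,
        np.zeros(len(clean.baseline)),
        clean.outcomes.set_index("recruit_id").loc[clean.baseline["recruit_id"], "day"],
        clean.outcomes.set_index("recruit_id").loc[clean.baseline["recruit_id"], "event"],
        ties=ties,
    )
    lp0 = xb.to_numpy() @ base_fit.params.to_numpy()
    # constant over landmarks; replicate on the supermodel's row grid so the
    # evaluation uses identical case/control sets
    lp_base = lp_super[["recruit_id", "s"]].copy()
    lp_base["lp"] = (
        pd.Series(lp0, index=clean.baseline["recruit_id"]).reindex(lp_base["recruit_id"]).to_numpy()
    )

    n_landmarks = clean.duration_weeks - 1
    rows = []
    for t in eval_days:
        rows.append(
            {
                "day": int(t),
                "auc_supermodel": dynamic_auc(lp_super, clean.outcomes, t, window_days, n_landmarks),
                "auc_baseline": dynamic_auc(lp_base, clean.outcomes, t, window_days, n_landmarks),
            }
        )
    return pd.DataFrame(rows), supermodel, base_fit


def summarize_dropout_reasons(
    outcomes: pd.DataFrame,
    early_cutoff_weeks: int = 4,
    agree_threshold: float = 7,
) -> dict:
    """Registered-reason frequencies and the early-dropout exit-survey summary.

    For dropouts within the first ``early_cutoff_weeks`` weeks, an exit
    statement counts as a main reason when its response is at or above
    ``agree_threshold`` (multiple statements per recruit allowed); missing
    surveys are tallied separately.
    """
    exit_items = [c for c in outcomes.columns if c.startswith("exit_") and c != "exit_survey_missing"]
    drops = outcomes[outcomes["event"] == 1]
    early = drops[drops["day"] <= 7 * early_cutoff_weeks]
    missing = early[exit_items].isna().all(axis=1)
    counts = (early.loc[~missing, exit_items] >= agree_threshold).sum()
    return {
        "n_dropouts": int(len(drops)),
        "reason_counts": drops["reason"].value_counts().to_dict(),
        "n_early": int(len(early)),
        "early_fraction_of_dropouts": float(len(early) / len(drops)) if len(drops) else float("nan"),
        "statement_counts": counts.astype(int).to_dict(),
        "n_missing_survey": int(missing.sum()),
    }
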