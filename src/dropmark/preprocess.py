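"""Data cleaning: mean imputation, LOCF completion, pain dichotomization,
predictor screening, and left-truncation entry times.

Missing continuous baseline measurements are filled with the observed
column mean (single mean imputation); weekly self-report gaps are filled
with each recruit's last observed value (LOCF), with weeks before the
first observation left unavailable (delayed entry / left truncation).
Recruits who drop out before contributing any status observation are
excluded, as in the source analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import LIKERT_ITEMS

__all__ = [
    "CleanCohort",
    "mean_impute_baseline",
    "dichotomize_pain",
    "locf_complete",
    "screen_predictors",
    "determine_entry",
    "preprocess",
]

CONTINUOUS_BASELINE = ["age", "height_m", "body_mass_kg", "body_fat_pct",
                       "cooper_km", "pushups", "situps"]


@dataclass
class CleanCohort:
    """Preprocessed cohort ready for landmarking."""

    baseline: pd.DataFrame
    imputation_log: pd.DataFrame
    weekly: pd.DataFrame  # completed long table with one provenance column per item
    items: list[str]  # retained time-varying predictors (5 Likert items + 'pain')
    entry: pd.DataFrame  # recruit_id, entry_week
    exclusions: pd.DataFrame  # recruit_id, reason
    outcomes: pd.DataFrame
    screen_report: pd.DataFrame
    duration_weeks: int = 24
    pain_carry: str = "absorbing"

    @property
    def recruit_ids(self) -> np.ndarray:
        return self.entry["recruit_id"].to_numpy()


def mean_impute_baseline(
    baseline: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single mean imputation of continuous baseline columns.

    Education stays categorical ("unknown" is an explicit level, never
    imputed).  Returns the imputed table and a log of (recruit, column,
    fill value) for every imputed cell.
    """
    columns = columns if columns is not None else [c for c in CONTINUOUS_BASELINE if c in baseline]
    out = baseline.copy()
    log_rows = []
    for col in columns:
        vals = out[col]
        if len(out) and vals.isna().all():
            raise ValueError(f"baseline column {col!r} is entirely missing; cannot mean-impute")
        fill = float(vals.mean())
        miss = vals.isna()
        if miss.any():
            out.loc[miss, col] = fill
            for rid in out.loc[miss, "recruit_id"]:
                log_rows.append({"recruit_id": rid, "column": col, "fill_value": fill})
    log = pd.DataFrame(log_rows, columns=["recruit_id", "column", "fill_value"])
    return out, log


def dichotomize_pain(weekly: pd.DataFrame, carry: str = "absorbing") -> pd.DataFrame:
    """Binary weekly pain indicator from location marks and NPRS scores.

    A week scores 1 if any location was marked that week (any NPRS value),
    else 0.  With ``carry='absorbing'`` a recruit who ever reported pain
    keeps the indicator at 1 for all later observed weeks (ever-injured);
    with ``carry='locf'`` the raw weekly indicator is kept and gaps are
    filled downstream like any other item.
    """
    if carry not in ("absorbing", "locf"):
        raise ValueError("carry must be 'absorbing' or 'locf'")
    nprs = weekly["nprs"]
    bad = nprs.notna() & ((nprs < 0) | (nprs > 10))
    if bad.any():
        raise ValueError(f"NPRS values outside 0-10 found: {sorted(nprs[bad].unique())}")
    out = weekly.copy()
    out["pain"] = out["pain_reported"].astype(float)
    if carry == "absorbing":
        out = out.sort_values(["recruit_id", "week"], kind="stable")
        out["pain"] = out.groupby("recruit_id")["pain"].cummax()
        out = out.sort_index()
    return out


def locf_complete(
    weekly: pd.DataFrame,
    items: list[str],
    duration_weeks: int = 24,
) -> pd.DataFrame:
    """Complete the weekly table on a full recruit x week grid by LOCF.

    For each recruit and item, a missing week is filled with the most
    recent observed value from an earlier week; weeks before the first
    observation stay unavailable (NaN).  The returned long table carries a
    ``prov_<item>`` column per item with values in
    {"observed", "locf", "unavailable"}.  Observed cells are never changed,
    and applying the operation twice equals applying it once.
    """
    ids = weekly["recruit_id"].unique()
    weeks = np.arange(1, duration_weeks + 1)
    grid = pd.MultiIndex.from_product([ids, weeks], names=["recruit_id", "week"])
    out = pd.DataFrame(index=grid).reset_index()
    for item in items:
        wide = weekly.pivot_table(index="recruit_id", columns="week", values=item, aggfunc="first")
        wide = wide.reindex(index=ids, columns=weeks)
        observed = wide.notna()
        filled = wide.ffill(axis=1)
        prov = np.where(observed, "observed", np.where(filled.notna(), "locf", "unavailable"))
        out[item] = filled.to_numpy().ravel()
        out[f"prov_{item}"] = prov.ravel()
    return out


def screen_predictors(
    weekly: pd.DataFrame,
    outcomes: pd.DataFrame,
    items: list[str] | None = None,
    max_missing_frac: float = 0.5,
    min_variance: float = 1e-3,
) -> tuple[list[str], pd.DataFrame]:
    """Drop time-varying items with excessive pre-LOCF missingness or
    near-zero variance.

    The missing fraction of an item is 1 - observed / expected, where the
    expected count is the number of in-training recruit-weeks (a recruit
    contributes week w while ``7*(w-1) < day``).  An item is dropped iff
    its missing fraction strictly exceeds ``max_missing_frac`` or its
    observed variance is strictly below ``min_variance``.
    """
    items = items if items is not None else list(LIKERT_ITEMS)
    weeks_in_training = np.ceil(outcomes["day"] / 7).astype(int)
    expected = int(weeks_in_training.sum())
    rows = []
    kept = []
    for item in items:
        observed = int(weekly[item].notna().sum())
        miss_frac = 1.0 - observed / expected if expected else 1.0
        var = float(weekly[item].var(ddof=1)) if observed > 1 else 0.0
        drop = (miss_frac > max_missing_frac) or (var < min_variance)
        rows.append({"item": item, "missing_frac": miss_frac, "variance": var,
                     "kept": not drop})
        if not drop:
            kept.append(item)
    report = pd.DataFrame(rows)
    if not kept:
        raise ValueError("all time-varying predictors were screened out")
    return kept, report


def determine_entry(
    weekly: pd.DataFrame, outcomes: pd.DataFrame, items: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-recruit entry week (first week with any observed status) and
    exclusions for recruits whose dropout precedes any observation."""
    items = items if items is not None else [c for c in LIKERT_ITEMS if c in weekly]
    has_obs = weekly[items].notna().any(axis=1)
    first = (
        weekly.loc[has_obs].groupby("recruit_id")["week"].min().rename("entry_week")
    )
    out = outcomes.set_index("recruit_id")
    entry = first.reindex(out.index)
    # dropout before the first observation (or no observation at all)
    no_obs = entry.isna() | ((out["event"] == 1) & (out["day"] <= 7 * (entry - 1)))
    exclusions = pd.DataFrame(
        {"recruit_id": out.index[no_obs], "reason": "no_observations"}
    ).reset_index(drop=True)
    entry_df = (
        entry[~no_obs].astype(int).reset_index().rename(columns={"index": "recruit_id"})
    )
    return entry_df, exclusions


def preprocess(
    cohort,
    max_missing_frac: float = 0.5,
    min_variance: float = 1e-3,
    pain_carry: str = "absorbing",
) -> CleanCohort:
    """Run the full cleaning chain on a (possibly degraded) simulated cohort."""
    baseline, log = mean_impute_baseline(cohort.baseline)
    weekly = dichotomize_pain(cohort.weekly, carry=pain_carry)
    kept_items, report = screen_predictors(
        weekly, cohort.outcomes, max_missing_frac=max_missing_frac, min_variance=min_variance
    )
    items = kept_items + ["pain"]
    duration = cohort.config.duration_weeks
    entry, exclusions = determine_entry(weekly, cohort.outcomes, items=kept_items)
    completed = locf_complete(weekly, items, duration_weeks=duration)

    keep_ids = set(entry["recruit_id"])
    baseline = baseline[baseline["recruit_id"].isin(keep_ids)].reset_index(drop=True)
    completed = completed[completed["recruit_id"].isin(keep_ids)].reset_index(drop=True)
    outcomes = cohort.outcomes[cohort.outcomes["recruit_id"].isin(keep_ids)].reset_index(drop=True)

    return CleanCohort(
        baseline=baseline,
        imputation_log=log,
        weekly=completed,
        items=items,
        entry=entry,
        exclusions=exclusions,
        outcomes=outcomes,
        screen_report=report,
        duration_weeks=duration,
        pain_carry=pain_carry,
    )
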