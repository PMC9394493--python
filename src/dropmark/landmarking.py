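"""Landmark grid, per-landmark risk sets and the stacked supermodel dataset.

A 24-week course yields S = 23 nonoverlapping weekly landmarks at days
7, 14, ..., 161, each predicting over a one-week horizon.  A recruit
contributes a row at landmark s iff they are still in training at day 7s
and entered (first observed status) at or before week s; the row's event
indicator is 1 iff the dropout day falls in (7s, 7(s+1)].  Stacking over
landmarks gives the supermodel dataset: events occupy disjoint time
windows, so a single day-timescale partial likelihood with (start, stop]
risk intervals forms risk sets within each window automatically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BASELINE_COLS, build_design  # noqa: F401  (re-exported for callers)
from .preprocess import CleanCohort

__all__ = ["landmark_grid", "build_landmark_dataset", "stack_landmarks", "last_landmark_at_risk"]

_RAW_BASELINE = ["age", "height_m", "body_mass_kg", "body_fat_pct",
                 "cooper_km", "pushups", "situps", "education"]


def landmark_grid(duration_weeks: int) -> pd.DataFrame:
    """Weekly landmark grid: S = duration_weeks - 1 landmarks at days 7s."""
    if duration_weeks < 2:
        raise ValueError("duration_weeks must be at least 2 to define a landmark")
    s = np.arange(1, duration_weeks)
    return pd.DataFrame({"s": s, "day": 7 * s, "horizon_day": 7 * (s + 1)})


def last_landmark_at_risk(day: np.ndarray, n_landmarks: int) -> np.ndarray:
    """Last landmark index at which a recruit with exit ``day`` is at risk.

    At risk at s requires day > 7s, so the last landmark is ceil(day/7) - 1,
    capped at S.  Exits at or before day 7 yield 0 (no landmark).
    """
    return np.minimum(np.ceil(np.asarray(day) / 7).astype(int) - 1, n_landmarks)


def _landmark_rows(clean: CleanCohort, s_values: np.ndarray) -> pd.DataFrame:
    out = clean.outcomes.set_index("recruit_id")
    entry = clean.entry.set_index("recruit_id")["entry_week"]
    weekly = clean.weekly.set_index(["recruit_id", "week"])

    frames = []
    for s in s_values:
        day_lm, day_hz = 7 * s, 7 * (s + 1)
        in_training = out["day"] > day_lm
        entered = entry.reindex(out.index) <= s
        ids = out.index[in_training & entered.fillna(False)].to_numpy()
        if len(ids) == 0:
            continue
        idx = pd.MultiIndex.from_arrays(
            [ids, np.full(len(ids), s)], names=["recruit_id", "week"]
        )
        z = weekly.reindex(idx)[clean.items]
        # LOCF could not supply a value: the recruit-landmark row is absent
        avail = z.notna().all(axis=1).to_numpy()
        ids = np.asarray(ids)[avail]
        if len(ids) == 0:
            continue
        z = z[avail].reset_index(drop=True)
        o = out.loc[ids]
        event = ((o["event"] == 1) & (o["day"] <= day_hz)).astype(int).to_numpy()
        stop = np.where(event == 1, o["day"].to_numpy(), day_hz)
        rows = pd.DataFrame({
            "recruit_id": ids,
            "s": s,
            "start": day_lm,
            "stop": stop,
            "event": event,
        })
        frames.append(pd.concat([rows, z], axis=1))
    if not frames:
        return pd.DataFrame(columns=["recruit_id", "s", "start", "stop", "event", *clean.items])
    return pd.concat(frames, ignore_index=True)


def build_landmark_dataset(clean: CleanCohort, s: int) -> pd.DataFrame:
    """Risk-set rows for one landmark, with baseline covariates merged in."""
    S = clean.duration_weeks - 1
    if not 1 <= s <= S:
        raise ValueError(f"landmark s={s} outside grid 1..{S}")
    rows = _landmark_rows(clean, np.array([s]))
    return rows.merge(clean.baseline[["recruit_id", *_RAW_BASELINE]], on="recruit_id")


def stack_landmarks(clean: CleanCohort, grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Concatenate all landmark datasets into the supermodel table.

    Columns: recruit id, landmark ``s``, the (start, stop] risk interval in
    days, the window event indicator, the time-varying item values at the
    landmark, and the raw baseline covariates.  Each dropout after day 7
    carries event = 1 in exactly one row.
    """
    grid = grid if grid is not None else landmark_grid(clean.duration_weeks)
    stacked = _landmark_rows(clean, grid["s"].to_numpy())
    if stacked.empty:
        raise ValueError("every landmark has an empty risk set")
    stacked = stacked.merge(clean.baseline[["recruit_id", *_RAW_BASELINE]], on="recruit_id")
    return stacked.sort_values(["s", "recruit_id"], kind="stable").reset_index(drop=True)
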