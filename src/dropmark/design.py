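"""Canonical predictor layout and reference-centered design matrices.

The supermodel uses 21 predictors: 9 fixed baseline terms (gamma), 6
time-varying weekly self-report terms (beta1), and 6 landmark-interaction
terms (beta2).  All design columns are centered at a fixed reference
subject so that the reference's linear predictor is exactly zero at every
landmark; the Breslow baseline hazard then belongs to that subject.

The reference subject: a 23-year-old, 1.80 m, 80 kg, 14% body fat, 2.8 km
Cooper run, 55 push-ups and 55 sit-ups, education category "unknown",
neutral (5) on every weekly item and no reported pain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# Baseline design columns, in the order of the coefficient table.
BASELINE_COLS = [
    "height_m",
    "body_mass_kg",
    "age",
    "education_1",
    "education_2",
    "body_fat_pct",
    "cooper_km",
    "pushups_per10",
    "situps_per10",
]

# Time-varying columns entering the model (the sixth weekly item, mental
# fitness, is screened out in the paper-analogous pipeline and carries no
# true effect in the generator).
TV_COLS = ["health", "motivated", "soreness", "sleep", "physfit", "pain"]

INTERACTION_COLS = [f"{c}_x_landmark" for c in TV_COLS]

DESIGN_COLS = BASELINE_COLS + TV_COLS + INTERACTION_COLS

#: All weekly Likert items as generated (mental fitness included).
LIKERT_ITEMS = ["health", "motivated", "soreness", "sleep", "mentalfit", "physfit"]

EDUCATION_LEVELS = ["level_1", "level_2", "unknown"]

#: Reference subject in raw units (push-ups/sit-ups as repetition counts).
REFERENCE_SUBJECT: dict[str, float | str] = {
    "age": 23.0,
    "height_m": 1.80,
    "body_mass_kg": 80.0,
    "body_fat_pct": 14.0,
    "cooper_km": 2.8,
    "pushups": 55.0,
    "situps": 55.0,
    "education": "unknown",
    "health": 5.0,
    "motivated": 5.0,
    "soreness": 5.0,
    "sleep": 5.0,
    "mentalfit": 5.0,
    "physfit": 5.0,
    "pain": 0.0,
}


def landmark_code(s, coding: str = "s_minus_1"):
    """Numeric code of landmark ``s`` used in the interaction terms.

    ``s_minus_1`` (default) makes the main time-varying effect the effect at
    the first landmark; ``s`` codes the raw 1-based landmark index.
    """
    s = np.asarray(s, dtype=float)
    if coding == "s_minus_1":
        out = s - 1.0
    elif coding == "s":
        out = s
    else:
        raise ValueError(f"unknown landmark coding {coding!r}")
    return out if out.ndim else float(out)


def _education_dummies(education: pd.Series) -> pd.DataFrame:
    bad = ~education.isin(EDUCATION_LEVELS) & education.notna()
    if bad.any():
        raise ValueError(f"unknown education levels: {sorted(education[bad].unique())}")
    return pd.DataFrame(
        {
            "education_1": (education == "level_1").astype(float),
            "education_2": (education == "level_2").astype(float),
        },
        index=education.index,
    )


def baseline_design(baseline: pd.DataFrame) -> pd.DataFrame:
    """Reference-centered 9-column baseline design from a raw baseline table.

    Expects columns ``age, height_m, body_mass_kg, body_fat_pct, cooper_km,
    pushups, situps, education``; push-ups and sit-ups are rescaled to units
    of 10 repetitions as in the coefficient table.
    """
    ref = REFERENCE_SUBJECT
    out = pd.DataFrame(index=baseline.index)
    out["height_m"] = baseline["height_m"] - ref["height_m"]
    out["body_mass_kg"] = baseline["body_mass_kg"] - ref["body_mass_kg"]
    out["age"] = baseline["age"] - ref["age"]
    edu = _education_dummies(baseline["education"])
    out["education_1"] = edu["education_1"]
    out["education_2"] = edu["education_2"]
    out["body_fat_pct"] = baseline["body_fat_pct"] - ref["body_fat_pct"]
    out["cooper_km"] = baseline["cooper_km"] - ref["cooper_km"]
    out["pushups_per10"] = (baseline["pushups"] - ref["pushups"]) / 10.0
    out["situps_per10"] = (baseline["situps"] - ref["situps"]) / 10.0
    return out[BASELINE_COLS]


def tv_design(values: pd.DataFrame, tv_cols: Sequence[str] = TV_COLS) -> pd.DataFrame:
    """Reference-centered time-varying design (Likert items minus 5, pain minus 0)."""
    ref = REFERENCE_SUBJECT
    out = pd.DataFrame(index=values.index)
    for c in tv_cols:
        out[c] = values[c].astype(float) - float(ref[c])
    return out


def build_design(
    stacked: pd.DataFrame,
    coding: str = "s_minus_1",
    tv_cols: Sequence[str] = TV_COLS,
) -> pd.DataFrame:
    """Assemble the full 21-column centered design from a stacked landmark table.

    ``stacked`` must contain the raw baseline columns, the time-varying item
    values at each row's landmark, and the landmark index ``s``.  Interaction
    columns are ``(Z - Z_ref) * code(s)`` so the reference subject scores 0
    in every column at every landmark.
    """
    xb = baseline_design(stacked)
    zc = tv_design(stacked, tv_cols)
    code = landmark_code(stacked["s"].to_numpy(), coding)
    inter = zc.mul(code, axis=0)
    inter.columns = [f"{c}_x_landmark" for c in zc.columns]
    return pd.concat([xb, zc, inter], axis=1)


@dataclass(frozen=True)
class CoefficientSet:
    """The supermodel's 21 coefficients on the log-hazard-ratio scale.

    ``gamma`` holds the 9 baseline effects, ``beta1`` the 6 time-varying
    main effects (at landmark code 0) and ``beta2`` the 6 per-landmark
    interaction slopes.
    """

    values: pd.Series

    def __post_init__(self) -> None:
        v = self.values.reindex(DESIGN_COLS)
        if v.isna().any():
            missing = list(v.index[v.isna()])
            raise ValueError(f"coefficient set is missing terms: {missing}")
        if not np.isfinite(v.to_numpy()).all():
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "values", v.astype(float))

    @property
    def gamma(self) -> pd.Series:
        return self.values[BASELINE_COLS]

    @property
    def beta1(self) -> pd.Series:
        return self.values[TV_COLS]

    @property
    def beta2(self) -> pd.Series:
        s = self.values[INTERACTION_COLS].copy()
        s.index = TV_COLS
        return s

    @classmethod
    def from_hazard_ratios(cls, hr: Mapping[str, float]) -> "CoefficientSet":
        return cls(pd.Series({k: float(np.log(v)) for k, v in hr.items()}))


def subject_design_row(subject: Mapping[str, float | str], s: int, coding: str = "s_minus_1") -> pd.Series:
    """Centered 21-vector for one subject's raw covariates at landmark ``s``.

    Raises :class:`KeyError`-derived errors naming any missing covariate.
    """
    required = ["height_m", "body_mass_kg", "age", "education", "body_fat_pct",
                "cooper_km", "pushups", "situps"] + TV_COLS
    missing = [k for k in required if k not in subject or subject[k] is None]
    if missing:
        raise ValueError(f"subject is missing covariates: {missing}")
    row = {k: subject[k] for k in required}
    df = pd.DataFrame([row])
    df["s"] = s
    return build_design(df, coding=coding).iloc[0]
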